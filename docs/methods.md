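# Methods

## The model family

All six models describe a dimensionless transmembrane voltage u(t) of a
single cardiac cell driven by a pacing stimulus,

    du/dt = I_tot(u, gates; p) + I_stim(t),

where I_tot collects the model's phenomenological currents and the gates
are one to three auxiliary recovery variables.  The implemented models and
their sources:

| model | variables | parameters | origin |
|-------|-----------|------------|--------|
| MS    | u, h      | 5  | Mitchell & Schaeffer (2003) |
| MMS   | u, h      | 5  | Corrado & Niederer (2016) variant of MS |
| MFHN  | u, v      | 5  | Rogers & McCulloch (1994) modified FitzHugh–Nagumo |
| FK    | u, v, w   | 13 | Fenton & Karma (1998) three-current model; the Beeler–Reuter-derived constant set is the default |
| BOCF  | u, v, w, s | 27 | Bueno-Orovio, Cherry & Fenton (2008) minimal human ventricular model, epicardial set |
| BBOCF | u, v, w, s | 33 | BOCF with two split time scales for saddleback ("Brugada-type") morphologies |

Design choices where the family definition was genuinely open:

* **BOCF roster.** The original publication lists 28 constants.  The
  resting-offset u_o multiplies nothing that matters at the resting state
  we use (u_rest = 0), so it is fixed at 0 and excluded from fitting,
  leaving 27 fittable parameters.
* **BBOCF construction.** The Brugada variant replaces the constant
  tau_w+ with a voltage-dependent sigmoidal blend between tau_w1+ and
  tau_w2+ (steepness k_w+, centre u_w+) and the constant tau_si with an
  s-gate-dependent blend between tau_si1 and tau_si2 (k_si, centre s_c).
  The defaults make both blends degenerate, so the default BBOCF
  reproduces the BOCF epicardial dynamics exactly; the extra parameters
  only matter when the fitter separates them.
* **Heaviside convention.** Every gating regime switches on the closed
  side of its threshold: the supra-threshold branch applies for
  u >= threshold.  This is applied identically in the reference
  right-hand sides and the compiled kernels.
* **Rest states.** Analytic resting equilibria are used: u = 0 with every
  gate at its u = 0 steady state.  For FK the slow-inward tanh has a tail
  at u = 0, so the exact rest voltage solves
  u = tau_0 (1 + tanh(k(u − u_csi)))/(2 tau_si) (about 1e−8 for the
  defaults); for BOCF/BBOCF the s gate rests at (1 + tanh(−k_s u_s))/2.
* **Default bounds.** The per-parameter fitting bounds ship with the model
  registry and bracket each default by a physiologically plausible margin
  (roughly half to a few times the default for time constants, and the
  meaningful sub-interval of [0, 1] for thresholds).  They are deliberately
  wide enough that the swarm, not the box, does the work.

## Pacing and integration

Models are paced by a square stimulus current (default 0.2 ms^-1 for
2 ms; a two-phase "biphasic" surrogate waveform — a negative fraction of
the pulse followed by the positive phase — is available behind the same
interface and is considered experimental).  Each stimulus fires at the
start of its cycle.  Integration is forward Euler with a default step of
dt = 0.02 ms; voltage is sampled every 1 ms starting at the onset of the
first recorded beat, after a configurable number of unrecorded
pre-recording beats that wash out the initial-condition transient.

Numerical choices:

* Explicit Euler is conditionally stable, and the swarm explores parameter
  corners where it diverges.  A trace whose state leaves the finite range
  (or |u| > 1e3) is flagged invalid rather than raising; the fitness layer
  maps it to a finite worst-case sentinel so the swarm ordering among valid
  particles is untouched.
* Batch integration over thousands of parameter sets is the hot loop; it
  runs in compiled kernels that iterate time-outer/particle-inner over
  contiguous per-variable arrays (single-row integration is the same
  kernel with batch size 1, so results are identical by construction).
  Sub-threshold particles decay exponentially for hundreds of
  milliseconds; their voltages are flushed to zero below 1e−280 because
  letting them enter the denormal range stalls the SIMD batch by an order
  of magnitude.  The kernels use strict IEEE arithmetic — fast-math
  relaxations are avoided deliberately, since the no-NaN assumption would
  disable the blow-up detection.
* The Euler trajectories at dt = 0.02 agree with an adaptive
  high-order Runge–Kutta reference (DOP853, rtol 1e−10, restarted at
  stimulus discontinuities) to a few times 1e−3 on the voltage over two
  beats, with the expected first-order convergence in dt.

## Fitness

Voltage datasets are compared after two preprocessing steps: the data are
affinely normalized to min 0 / max "normalize-to" (0 bypasses; BOCF-family
fits default to 1.35 because the model's plateau overshoots 1), and the
first upstrokes of model and data are aligned by matching the first sample
at or above half of each trace's maximum.  The error is the sum of squared
differences over the overlapping samples divided by the full data length —
a mean-square per sample, so longer recordings do not dominate, and
truncated overlap after alignment is implicitly penalized.  APD datasets
contribute the raw sum of squared APD differences in ms^2 (not divided by
the APD count; treated as a dialect flag); each expected-but-missing model
AP contributes one squared cycle length, the largest possible squared
error.  APDs are measured at a user threshold on the normalized voltage
scale (0.1 on unit-normalized data = APD90) with linear interpolation of
the crossing times.  The total fitness is the weighted sum of dataset
errors; any invalid component makes the whole particle worst-case.

Self-fit data generated by the model itself are already on the model's
voltage scale, so those fits bypass normalization (normalize-to 0).

## The swarm

Constriction-coefficient PSO: positions initialized uniformly inside the
bounds, velocities at zero (the first move is then governed purely by the
best-attraction terms), and per iteration

    v <- chi [ v + u(0, phi1) (.) (b_i − p) + u(0, phi2) (.) (b − p) ],
    p <- p + gamma v,

with phi1 = phi2 = 2.05, chi = 2/(phi − 2 + sqrt(phi^2 − 4 phi)) ≈ 0.73
(phi = phi1 + phi2), learning rate gamma = 0.05, and u(a, b) elementwise
uniform on the half-open interval [a, b).  A coordinate that leaves its
range is redrawn uniformly from the three-quarters of the range adjacent
to the violated bound; only that coordinate changes and its velocity
component is kept (dialect choice).  Personal/global bests keep the
incumbent on ties.  Termination is a fixed iteration count.  One seeded
NumPy generator drives initialization, the velocity draws and the bound
resets, so a seed reproduces a run bit for bit; the seed is recorded in
the run-details output.

## Synthetic data

The generator emulates steady-state pacing: the model is paced from rest
one beat at a time until the APD (at half the first beat's peak) changes
by less than 0.5 ms between consecutive beats, or until a stable period-2
pattern appears (beat k vs k−2 within tolerance), capped at 200 beats with
a warning.  The requested beats are then recorded at 1 ms, written one
voltage per line with a JSON sidecar holding the generating parameters and
the recording metadata.  Optional additive Gaussian noise is seeded.  A
period-2 steady state is labelled alternans only when the beat-to-beat
alternation exceeds 5% of the APD, so damped convergence ripple is not
mislabelled.

What the generator does not emulate: measurement noise structure of
microelectrode or optical-mapping recordings (baseline drift, upstroke
blunting, motion artefacts), cell-to-cell variability, or data from
biophysically detailed ionic models.  Passing self-fit tests therefore
demonstrates parameter recovery under the model's own dynamics, not
robustness to experimental artefacts.

## Identifiability analysis

Repeated independent fits (seeds base .. base+R−1) give R best-fit
vectors.  Parameters are examined normalized over their bounds; spread
(SD) across runs measures how well the data constrain each parameter.
Ensembles are compared by counting SD reductions and by per-parameter
two-sample t-tests on the raw values with a strict p < 0.001 band and a
borderline 0.001–0.01 band — a small alpha standing in for an explicit
multiple-testing correction.  The Welch (unequal-variance) form is the
default, with the pooled form behind a flag; zero-variance/equal-mean
pairs are "not-different" by convention.

## Problem sizes used by the test suite

The repeated-fit experiments in the test suite run at deliberately scaled
problem sizes chosen once for this package: data generation and fitting
share a forward-Euler step of 0.2 ms (so the discretization cancels in
self-fits), MS self-fits use cycle lengths 500/400/300 ms with two
recorded beats after 16 pre-recording beats, 20 swarms of 1024 particles
for 100 iterations; the FK particle-scaling comparison uses one cycle
length, 32 iterations and five seeds per particle count.  The 16
pre-recording beats matter: the MS model approaches its paced steady state
slowly at short cycle lengths (tens of beats at CL 300 ms), and recording
the model mid-transient against steady-state data floors the error and
biases the recovered parameters.  The integrator-accuracy checks always
run at the default dt = 0.02 ms.

## Known limitations

* Each cycle length restarts from rest; state carry-over across datasets
  is available programmatically but off by default, so rate-history
  effects spanning CL changes are not modelled.
* The upstroke-alignment criterion (half of the trace maximum) is a
  documented choice; data whose first upstroke is clipped or whose peak is
  an artefact will align poorly.
* The biphasic stimulus is a surrogate waveform, not a calibrated
  diffusive-coupling current.
* Fixed-iteration termination only; no convergence-threshold stopping.
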