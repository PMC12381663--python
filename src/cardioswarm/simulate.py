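"""Pacing-protocol simulation of the action-potential models.

A model is paced with a periodic stimulus train at a fixed cycle length (CL)
and integrated with the forward Euler method (default step 0.02 ms).  The
first ``n_prerecording`` beats wash out initial-condition transients; the
voltage of the following ``n_stimuli`` beats is recorded on a regular
sampling grid (default 1 ms), yielding a :class:`Trace` directly comparable
to newline-delimited data files.

Conventions:

* each stimulus fires at the start of its cycle;
* samples are taken at t = 0, sample_interval, 2*sample_interval, ...
  measured from the onset of the first *recorded* stimulus;
* every cycle starts from the state left by the previous one; independent
  cycle lengths each restart from the resting state unless an initial state
  is passed explicitly.

If a particle's state becomes non-finite (possible under extreme
parameter combinations proposed by the optimizer, since explicit Euler is
conditionally stable), the trace is flagged invalid rather than raising;
the fitness layer maps invalid traces to a worst-case error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import models as _models
from ._kernels import KERNELS
from .errors import ConfigurationError

__all__ = [
    "StimulusSpec",
    "PacingProtocol",
    "Trace",
    "TraceBatch",
    "stimulus_current",
    "integrate",
    "integrate_batch",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class StimulusSpec:
    """External stimulus current waveform.

    ``square``: constant ``magnitude`` (1/ms) for ``duration`` ms, 0 after.

    ``biphasic``: an experimental surrogate for the upstroke-inducing
    current experienced through diffusive coupling: a negative phase of
    amplitude ``-neg_scale * magnitude`` for the first
    ``neg_fraction * duration`` ms followed by a positive phase of amplitude
    ``magnitude``.
    """

    shape: str = "square"
    magnitude: float = 0.2
    duration: float = 2.0
    neg_fraction: float = 0.5
    neg_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in ("square", "biphasic"):
            raise ConfigurationError(f"unknown stimulus shape {self.shape!r}")
        if self.magnitude < 0:
            raise ConfigurationError("stimulus magnitude must be non-negative")
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be positive")
        if not 0.0 <= self.neg_fraction < 1.0:
            raise ConfigurationError("neg_fraction must lie in [0, 1)")


def stimulus_current(stimulus: StimulusSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Stimulus current (1/ms) at time ``t`` (ms) since stimulus onset."""
    t = np.asarray(t, dtype=float)
    if stimulus.shape == "square":
        out = np.where((t >= 0) & (t < stimulus.duration), stimulus.magnitude, 0.0)
    else:
        t_neg = stimulus.neg_fraction * stimulus.duration
        out = np.where(
            (t >= 0) & (t < t_neg),
            -stimulus.neg_scale * stimulus.magnitude,
            np.where((t >= t_neg) & (t < stimulus.duration), stimulus.magnitude, 0.0),
        )
    return float(out) if out.ndim == 0 else out


def _as_steps(value: float, dt: float, what: str) -> int:
    steps = value / dt
    rounded = round(steps)
    if abs(steps - rounded) > 1e-9 * max(1.0, abs(steps)) or rounded <= 0:
        raise ConfigurationError(
            f"{what} ({value} ms) must be a positive integer multiple of dt ({dt} ms)"
        )
    return int(rounded)


@dataclass(frozen=True)
class PacingProtocol:
    """Stimulus timing: cycle length, beat counts, steps and sampling grid."""

    cycle_length: float
    n_stimuli: int
    n_prerecording: int = 0
    dt: float = 0.02
    sample_interval: float = 1.0
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def __post_init__(self) -> None:
        if self.cycle_length <= self.stimulus.duration:
            raise ConfigurationError(
                "cycle length must exceed the stimulus duration"
            )
        if self.n_stimuli < 1:
            raise ConfigurationError("n_stimuli must be >= 1")
        if self.n_prerecording < 0:
            raise ConfigurationError("n_prerecording must be >= 0")
        # these raise if the grid does not divide evenly
        _as_steps(self.sample_interval, self.dt, "sample interval")
        _as_steps(self.cycle_length, self.dt, "cycle length")
        _as_steps(self.cycle_length, self.sample_interval, "cycle length")

    @property
    def steps_per_cycle(self) -> int:
        return _as_steps(self.cycle_length, self.dt, "cycle length")

    @property
    def sample_stride(self) -> int:
        return _as_steps(self.sample_interval, self.dt, "sample interval")

    @property
    def n_samples(self) -> int:
        return self.n_stimuli * _as_steps(
            self.cycle_length, self.sample_interval, "cycle length"
        )

    def with_cycle_length(self, cycle_length: float) -> "PacingProtocol":
        return replace(self, cycle_length=cycle_length)

    def stimulus_steps(self) -> np.ndarray:
        """Per-step stimulus current over all pre-recording + recorded beats."""
        n_total = (self.n_prerecording + self.n_stimuli) * self.steps_per_cycle
        t = (np.arange(n_total) * self.dt) % self.cycle_length
        return np.ascontiguousarray(
            stimulus_current(self.stimulus, t), dtype=np.float64
        )


@dataclass
class Trace:
    """A sampled voltage time series at one cycle length."""

    values: np.ndarray
    sample_interval: float
    cycle_length: float
    valid: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.sample_interval


@dataclass
class TraceBatch:
    """Voltage traces for a batch of parameter vectors under one protocol.

    Row ``i`` is exactly the trace :func:`integrate` would produce for
    parameter row ``i`` (batching is a performance device, not a semantic
    one).  Indexing returns the corresponding :class:`Trace`.
    """

    values: np.ndarray  # (P, n_samples)
    valid: np.ndarray  # (P,) bool
    sample_interval: float
    cycle_length: float
    final_states: np.ndarray  # (P, state_dim)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> Trace:
        return Trace(
            self.values[i].copy(),
            self.sample_interval,
            self.cycle_length,
            bool(self.valid[i]),
        )


def integrate_batch(
    model: _models.ModelSpec | str,
    param_matrix: np.ndarray,
    protocol: PacingProtocol,
    initial_states: np.ndarray | None = None,
) -> TraceBatch:
    """Forward-Euler pace a batch of parameter vectors under one protocol."""
    spec = _models.get_model(model) if isinstance(model, str) else model
    param_matrix = np.ascontiguousarray(param_matrix, dtype=np.float64)
    if param_matrix.ndim != 2 or param_matrix.shape[1] != spec.n_parameters:
        raise ConfigurationError(
            f"parameter matrix must be (P, {spec.n_parameters}) for model "
            f"{spec.name}, got {param_matrix.shape}"
        )
    P = param_matrix.shape[0]
    if initial_states is None:
        states = np.empty((P, spec.state_dim))
        for i in range(P):
            states[i] = _models.rest_state(spec, param_matrix[i])
        states = np.ascontiguousarray(states)
    else:
        states = np.ascontiguousarray(initial_states, dtype=np.float64).copy()
        if states.shape != (P, spec.state_dim):
            raise ConfigurationError(
                f"initial states must be (P, {spec.state_dim}), got {states.shape}"
            )
    istim = protocol.stimulus_steps()
    record_start = protocol.n_prerecording * protocol.steps_per_cycle
    out = np.empty((P, protocol.n_samples))
    valid = np.ones(P, dtype=np.bool_)
    KERNELS[spec.name](
        states,
        param_matrix,
        istim,
        protocol.dt,
        record_start,
        protocol.sample_stride,
        out,
        valid,
    )
    # a blow-up after the final sample still invalidates the trace
    bad = ~np.all(np.isfinite(states), axis=1) | (np.abs(states[:, 0]) >= 1e3)
    if bad.any():
        valid[bad] = False
        states[bad] = 0.0
    return TraceBatch(out, valid, protocol.sample_interval, protocol.cycle_length, states)


def integrate(
    model: _models.ModelSpec | str,
    params: np.ndarray,
    protocol: PacingProtocol,
    initial_state: np.ndarray | None = None,
    return_final_state: bool = False,
):
    """Pace a single parameter vector; see :func:`integrate_batch`."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    init = None if initial_state is None else np.atleast_2d(initial_state)
    batch = integrate_batch(model, params, protocol, init)
    trace = batch[0]
    if return_final_state:
        return trace, batch.final_states[0]
    return trace


def write_trace(path: str, trace: Trace, fmt: str = "%.9g") -> None:
    """Write a trace in the newline-delimited dialect (one voltage per line)."""
    np.savetxt(path, trace.values, fmt=fmt)


def read_trace(path: str, sample_interval: float, cycle_length: float) -> Trace:
    """Read a newline-delimited voltage file."""
    values = np.loadtxt(path, dtype=float, ndmin=1)
    return Trace(values, sample_interval, cycle_length)
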