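"""Synthetic fixture datasets: a model paced to steady state at chosen CLs.

For parameter-recovery ("self-fit") studies the data are produced by the
model itself with known parameters: the model is paced from rest at a fixed
cycle length until the action potential duration stabilizes, and only then
are the requested beats recorded, emulating experimental steady-state
pacing.  Files use the same newline-delimited dialect (one voltage per
line, fixed sample interval) that the fitting front-end consumes, with a
JSON sidecar carrying the generating truth and the recording metadata.

Steady state means the APD (measured at half the first beat's peak, with
sub-sample interpolation) changes by less than ``apd_tolerance`` between
consecutive beats; at cycle lengths producing alternans a stable period-2
pattern (beat k vs beat k-2) counts instead.  Pre-pacing is capped at
``max_prepacing_beats``; hitting the cap records the data anyway and warns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import models as _models
from .errors import GenerationError
from .fitness import measure_apds
from .simulate import PacingProtocol, StimulusSpec, Trace, integrate, write_trace

__all__ = ["SyntheticDatasetSpec", "SyntheticRecord", "generate"]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    model: str = "MS"
    params: tuple | None = None  # None = model defaults
    cycle_lengths: tuple = (500.0, 400.0, 300.0)
    n_recorded_stimuli: int = 2
    apd_tolerance: float = 0.5  # ms between consecutive-beat APDs
    max_prepacing_beats: int = 200
    dt: float = 0.02
    sample_interval: float = 1.0
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apd_tolerance <= 0:
            raise GenerationError("APD tolerance must be positive")
        if any(cl <= 0 for cl in self.cycle_lengths):
            raise GenerationError("cycle lengths must be positive")
        if self.n_recorded_stimuli < 1:
            raise GenerationError("need at least one recorded stimulus")


@dataclass
class SyntheticRecord:
    """One generated dataset: the trace, its CL and the generating truth."""

    trace: Trace
    cycle_length: float
    params: np.ndarray
    model_name: str
    n_prepacing_beats: int
    steady: bool
    alternans: bool
    apd_history: np.ndarray
    path: str | None = None


def _pace_to_steady_state(
    spec: SyntheticDatasetSpec, model: _models.ModelSpec, params: np.ndarray, cl: float
):
    protocol = PacingProtocol(
        cycle_length=cl,
        n_stimuli=1,
        n_prerecording=0,
        dt=spec.dt,
        sample_interval=spec.sample_interval,
        stimulus=spec.stimulus,
    )
    state = _models.rest_state(model, params)
    apds: list[float] = []
    threshold = None
    steady = False
    alternans = False
    beats = 0
    while beats < spec.max_prepacing_beats:
        trace, state = integrate(
            model, params, protocol, initial_state=state, return_final_state=True
        )
        beats += 1
        if threshold is None:
            peak = float(trace.values.max())
            if not trace.valid or peak < 0.1:
                raise GenerationError(
                    f"model {model.name} does not excite at CL {cl} ms "
                    "with the given parameters"
                )
            threshold = 0.5 * peak
        apd = measure_apds(trace, threshold, n_expected=1)
        apds.append(float(apd[0]) if apd.size else np.nan)
        if len(apds) >= 2 and abs(apds[-1] - apds[-2]) < spec.apd_tolerance:
            steady = True
            break
        if len(apds) >= 4 and abs(apds[-1] - apds[-3]) < spec.apd_tolerance and abs(
            apds[-2] - apds[-4]
        ) < spec.apd_tolerance:
            steady = True
            # call it alternans only when the beat-to-beat alternation is a
            # substantial fraction of the APD, not a damped residual ripple
            mean_apd = 0.5 * (apds[-1] + apds[-2])
            alternans = abs(apds[-1] - apds[-2]) > 0.05 * mean_apd
            break
    if not steady:
        warnings.warn(
            f"CL {cl} ms: APD not converged after {beats} pre-pacing beats "
            f"(last change {abs(apds[-1] - apds[-2]):.3g} ms); recording anyway",
            stacklevel=3,
        )
    return state, beats, steady, alternans, np.asarray(apds)


def generate(
    spec: SyntheticDatasetSpec, outdir: str | Path | None = None
) -> list[SyntheticRecord]:
    """Pace the model to steady state and record one dataset per CL."""
    model = _models.get_model(spec.model)
    params = (
        model.defaults if spec.params is None else np.asarray(spec.params, dtype=float)
    )
    rng = np.random.default_rng(spec.seed)
    records = []
    for cl in spec.cycle_lengths:
        state, beats, steady, alternans, apds = _pace_to_steady_state(
            spec, model, params, cl
        )
        protocol = PacingProtocol(
            cycle_length=cl,
            n_stimuli=spec.n_recorded_stimuli,
            n_prerecording=0,
            dt=spec.dt,
            sample_interval=spec.sample_interval,
            stimulus=spec.stimulus,
        )
        trace = integrate(model, params, protocol, initial_state=state)
        if spec.noise_sd > 0:
            trace.values = trace.values + rng.normal(
                0.0, spec.noise_sd, size=trace.values.shape
            )
        record = SyntheticRecord(
            trace=trace,
            cycle_length=cl,
            params=params,
            model_name=model.name,
            n_prepacing_beats=beats,
            steady=steady,
            alternans=alternans,
            apd_history=apds,
        )
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            stem = f"{model.name.lower()}_cl{cl:g}"
            data_path = outdir / f"{stem}.txt"
            write_trace(str(data_path), trace)
            sidecar = {
                "model": model.name,
                "cycle_length": cl,
                "sample_interval": spec.sample_interval,
                "n_stimuli": spec.n_recorded_stimuli,
                "dt": spec.dt,
                "stimulus": {
                    "shape": spec.stimulus.shape,
                    "magnitude": spec.stimulus.magnitude,
                    "duration": spec.stimulus.duration,
                },
                "noise_sd": spec.noise_sd,
                "seed": spec.seed,
                "n_prepacing_beats": beats,
                "steady": steady,
                "alternans": alternans,
                "apd_history_tail": apds[-4:].tolist(),
                "true_parameters": dict(
                    zip(model.parameter_names, map(float, params))
                ),
            }
            with open(outdir / f"{stem}.json", "w") as fh:
                json.dump(sidecar, fh, indent=1)
            record.path = str(data_path)
        records.append(record)
    return records
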