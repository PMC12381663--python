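"""Composite fitness of a candidate trace against voltage and/or APD data.

The fitness of a parametrization against one dataset is

* voltage data: the sum of squared differences between the model voltage
  and the (normalized) data over the aligned, overlapping samples, divided
  by the number of data samples.  The division implements the length
  weighting that keeps longer recordings (longer cycle lengths) from
  dominating the composite error;
* APD data: the sum of squared differences between measured model APDs and
  the provided APDs (ms^2), not divided by the APD count.

Before comparison the first upstroke of the model trace is aligned to the
first upstroke of the data: both crossing indices are detected at half the
respective trace maximum, and the model trace is shifted by their
difference.  The total fitness is the weighted sum of the per-dataset
errors.  Invalid traces, failed alignments and empty overlaps map to the
finite worst-case sentinel :data:`WORST_FITNESS`, which exceeds any error a
valid comparison can produce while preserving the ordering of valid
particles.

APDs are measured at a user threshold on the normalized voltage scale: a
trace normalized to 1 with threshold 0.1 yields APD90.  Crossing times are
interpolated linearly between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateDataError
from .simulate import Trace

__all__ = [
    "WORST_FITNESS",
    "NormalizationRule",
    "DatasetEntry",
    "normalize",
    "find_upstroke",
    "align_upstroke",
    "measure_apds",
    "dataset_error",
    "total_fitness",
    "batch_dataset_error",
]

WORST_FITNESS = 1e12
"""Finite sentinel for invalid/unalignable candidates (see module docstring)."""


@dataclass(frozen=True)
class NormalizationRule:
    """Affine rescaling of data to [0, target_max]; target_max = 0 bypasses."""

    target_max: float = 1.0

    def __post_init__(self) -> None:
        if self.target_max < 0:
            raise ConfigurationError("normalize-to value must be >= 0")


def normalize(values: np.ndarray, rule: NormalizationRule) -> np.ndarray:
    """Map values affinely to min 0 / max ``rule.target_max`` (0 = bypass)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateDataError("cannot normalize an empty sequence")
    if rule.target_max == 0:
        return values.copy()
    lo = values.min()
    hi = values.max()
    if hi <= lo:
        raise DegenerateDataError(
            "cannot normalize constant data (max equals min)"
        )
    return (values - lo) * (rule.target_max / (hi - lo))


@dataclass
class DatasetEntry:
    """One dataset to fit: a voltage trace or a list of APDs at one CL.

    ``values`` hold the (already normalized) voltages for kind='voltage';
    ``apd_values`` the target APDs in ms for kind='apd'.  ``weight`` is this
    dataset's multiplier in the composite fitness.
    """

    kind: str
    cycle_length: float
    weight: float = 1.0
    values: np.ndarray | None = None
    apd_values: np.ndarray | None = None
    apd_threshold: float = 0.1
    sample_interval: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("voltage", "apd"):
            raise ConfigurationError(f"unknown dataset kind {self.kind!r}")
        if self.weight <= 0:
            raise ConfigurationError("fitting weight must be positive")
        if self.kind == "voltage":
            if self.values is None or len(np.atleast_1d(self.values)) == 0:
                raise ConfigurationError("voltage dataset requires values")
            self.values = np.asarray(self.values, dtype=float)
        else:
            if self.apd_values is None or len(np.atleast_1d(self.apd_values)) == 0:
                raise ConfigurationError("APD dataset requires apd_values")
            self.apd_values = np.asarray(self.apd_values, dtype=float)
            if not 0.0 < self.apd_threshold:
                raise ConfigurationError("APD threshold must be positive")

    @classmethod
    def from_trace(
        cls,
        trace: Trace,
        rule: NormalizationRule | None = None,
        weight: float = 1.0,
        label: str = "",
    ) -> "DatasetEntry":
        values = trace.values
        if rule is not None:
            values = normalize(values, rule)
        return cls(
            kind="voltage",
            cycle_length=trace.cycle_length,
            weight=weight,
            values=values,
            sample_interval=trace.sample_interval,
            label=label,
        )

    @property
    def n_samples(self) -> int:
        return 0 if self.values is None else len(self.values)


def find_upstroke(values: np.ndarray, threshold: float | None = None) -> int | None:
    """Index of the first sample at or above the alignment threshold.

    The threshold defaults to half the trace maximum.  Returns None when the
    trace never reaches it (no upstroke, e.g. a sub-threshold or flat trace).
    """
    values = np.asarray(values, dtype=float)
    hi = values.max() if values.size else 0.0
    if not np.isfinite(hi) or hi <= 0.0:
        return None
    thr = 0.5 * hi if threshold is None else threshold
    above = values >= thr
    if not above.any():
        return None
    return int(np.argmax(above))


def align_upstroke(model_trace: Trace | np.ndarray, data_trace: Trace | np.ndarray) -> int | None:
    """Sample offset aligning the model's first upstroke to the data's.

    Positive offset means the data upstroke occurs later: model sample j is
    compared against data sample j + offset.  None signals alignment failure
    (either trace lacks an upstroke); callers map that to worst-case fitness.
    """
    mv = model_trace.values if isinstance(model_trace, Trace) else np.asarray(model_trace)
    dv = data_trace.values if isinstance(data_trace, Trace) else np.asarray(data_trace)
    im = find_upstroke(mv)
    idx = find_upstroke(dv)
    if im is None or idx is None:
        return None
    return idx - im


def measure_apds(
    trace: Trace | np.ndarray,
    threshold: float,
    n_expected: int | None = None,
    sample_interval: float | None = None,
) -> np.ndarray:
    """Action potential durations at a fixed voltage threshold, in ms.

    Each APD runs from an upward crossing of the threshold to the next
    downward crossing, with crossing times interpolated linearly between
    the bracketing samples.  An AP still above threshold when the trace
    ends is not counted.  At most ``n_expected`` durations are returned.
    """
    if isinstance(trace, Trace):
        values = trace.values
        dt_s = trace.sample_interval
    else:
        values = np.asarray(trace, dtype=float)
        if sample_interval is None:
            raise ConfigurationError("sample_interval required for raw arrays")
        dt_s = sample_interval
    if threshold <= 0:
        raise ConfigurationError("APD threshold must be positive")
    above = values >= threshold
    flips = np.diff(above.astype(np.int8))
    up_idx = np.flatnonzero(flips == 1)  # crossing between i and i+1
    down_idx = np.flatnonzero(flips == -1)
    apds = []
    for i_up in up_idx:
        later = down_idx[down_idx >= i_up]
        if later.size == 0:
            break
        i_dn = later[0]
        # linear interpolation of the crossing times
        t_up = i_up + (threshold - values[i_up]) / (values[i_up + 1] - values[i_up])
        t_dn = i_dn + (values[i_dn] - threshold) / (values[i_dn] - values[i_dn + 1])
        apds.append((t_dn - t_up) * dt_s)
        if n_expected is not None and len(apds) >= n_expected:
            break
    return np.asarray(apds, dtype=float)


def _voltage_error(model_values: np.ndarray, entry: DatasetEntry) -> float:
    offset = align_upstroke(model_values, entry.values)
    if offset is None:
        return WORST_FITNESS
    n_m = len(model_values)
    n_d = len(entry.values)
    lo_m = max(0, -offset)
    hi_m = min(n_m, n_d - offset)
    if hi_m <= lo_m:
        return WORST_FITNESS
    diff = model_values[lo_m:hi_m] - entry.values[lo_m + offset : hi_m + offset]
    # dividing by the full data length penalizes truncated overlap implicitly
    return float(np.dot(diff, diff) / n_d)


def _apd_error(model_values: np.ndarray, entry: DatasetEntry, sample_interval: float) -> float:
    target = entry.apd_values
    got = measure_apds(
        model_values,
        entry.apd_threshold,
        n_expected=len(target),
        sample_interval=sample_interval,
    )
    n = min(len(got), len(target))
    err = float(np.sum((got[:n] - target[:n]) ** 2))
    # each missing AP contributes the maximal squared duration error
    err += (len(target) - n) * entry.cycle_length**2
    return err


def dataset_error(model_trace: Trace, entry: DatasetEntry) -> float:
    """Unweighted error of one model trace against one dataset."""
    if entry.kind == "voltage" and not np.isclose(
        model_trace.sample_interval, entry.sample_interval
    ):
        raise ConfigurationError(
            "model trace and data sample intervals differ "
            f"({model_trace.sample_interval} vs {entry.sample_interval} ms)"
        )
    if not model_trace.valid:
        return WORST_FITNESS
    if entry.kind == "voltage":
        return _voltage_error(model_trace.values, entry)
    return _apd_error(model_trace.values, entry, model_trace.sample_interval)


def total_fitness(traces: list[Trace], entries: list[DatasetEntry]) -> float:
    """Weighted sum of per-dataset errors; worst case propagates unweighted."""
    if len(traces) != len(entries):
        raise ConfigurationError("need exactly one model trace per dataset")
    total = 0.0
    for trace, entry in zip(traces, entries):
        err = dataset_error(trace, entry)
        if err >= WORST_FITNESS:
            return WORST_FITNESS
        total += entry.weight * err
    return total


def batch_dataset_error(
    values: np.ndarray,
    valid: np.ndarray,
    entry: DatasetEntry,
    sample_interval: float,
) -> np.ndarray:
    """Vectorized :func:`dataset_error` over the rows of a trace batch."""
    P, n_m = values.shape
    out = np.full(P, WORST_FITNESS)
    ok = np.asarray(valid, dtype=bool).copy()
    if entry.kind == "apd":
        for p in np.flatnonzero(ok):
            out[p] = _apd_error(values[p], entry, sample_interval)
        return out

    data = entry.values
    n_d = len(data)
    data_idx = find_upstroke(data)
    if data_idx is None:
        raise DegenerateDataError(
            f"dataset {entry.label or '<unnamed>'} has no detectable upstroke"
        )
    hi = values.max(axis=1)
    ok &= np.isfinite(hi) & (hi > 0.0)
    model_idx = np.argmax(values >= 0.5 * hi[:, None], axis=1)
    offsets = data_idx - model_idx
    # group rows sharing an offset so each group is one vectorized slice
    for off in np.unique(offsets[ok]):
        rows = np.flatnonzero(ok & (offsets == off))
        lo_m = max(0, -off)
        hi_m = min(n_m, n_d - off)
        if hi_m <= lo_m:
            continue  # no overlap: stays worst-case
        diff = values[np.ix_(rows, np.arange(lo_m, hi_m))] - data[lo_m + off : hi_m + off]
        out[rows] = np.einsum("ij,ij->i", diff, diff) / n_d
    return out
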