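"""Repeated-fit identifiability analysis.

A single swarm fit returns one low-error parametrization, but different
seeds can land on visibly different parameter vectors that fit the data
almost equally well.  Repeating the fit R times (seeds base_seed ..
base_seed + R - 1) and examining the spread of each fitted parameter —
normalized over its bounds so different scales are comparable — measures
how well the data actually constrain that parameter.

Two ensembles (e.g. a single-CL fit vs a multi-CL fit, or fits to two
species' recordings) are compared by

* counting parameters whose standard deviation decreased, and
* a per-parameter two-sample t-test on the raw best values with a strict
  band (p < 0.001, "different") and a borderline band (0.001 <= p < 0.01),
  mirroring the convention of using a small alpha instead of an explicit
  multiple-testing correction when many parameters are compared at once.

The t-test defaults to the Welch (unequal variance) form; the pooled
variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .pso import FitProblem, FitResult, PSOHyperparameters, run_fit

__all__ = [
    "RepeatedFitResult",
    "repeated_fits",
    "sd_reduction_count",
    "pairwise_parameter_tests",
]


@dataclass
class RepeatedFitResult:
    """Best-fit parameter vectors over R independent seeded runs."""

    model_name: str
    parameter_names: list[str]  # fitted parameters only
    params: np.ndarray  # (R, d) raw best values
    errors: np.ndarray  # (R,)
    lower: np.ndarray  # (d,)
    upper: np.ndarray  # (d,)
    base_seed: int = 0
    truth: np.ndarray | None = None
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return self.params.shape[0]

    @property
    def normalized(self) -> np.ndarray:
        """Parameters mapped affinely from [lower, upper] to [0, 1]."""
        return (self.params - self.lower) / (self.upper - self.lower)

    def summary(self) -> pd.DataFrame:
        """Per-parameter mean/SD on raw and bounds-normalized scales."""
        norm = self.normalized
        data = {
            "parameter": self.parameter_names,
            "mean": self.params.mean(axis=0),
            "sd": self.params.std(axis=0, ddof=1) if self.n_runs > 1 else np.nan,
            "norm_mean": norm.mean(axis=0),
            "norm_sd": norm.std(axis=0, ddof=1) if self.n_runs > 1 else np.nan,
        }
        if self.truth is not None:
            data["truth"] = self.truth
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        """Per-run best parameters, one row per run (for violin plots etc.)."""
        df = pd.DataFrame(self.params, columns=self.parameter_names)
        df.insert(0, "run", np.arange(self.n_runs))
        df["error"] = self.errors
        df.to_csv(path, index=False)


def repeated_fits(
    problem: FitProblem,
    hyper: PSOHyperparameters,
    n_runs: int,
    base_seed: int = 0,
    truth: np.ndarray | None = None,
    callback=None,
) -> RepeatedFitResult:
    """R independent fits with seeds base_seed .. base_seed + R - 1.

    Individual run failures are recorded rather than fatal as long as at
    least two runs succeed (one run technically succeeds too, but leaves
    the spread statistics undefined, which ``summary`` marks with NaN SDs).
    """
    if n_runs < 1:
        raise ConfigurationError("need at least one run")
    results: list[FitResult] = []
    failures: list[tuple[int, str]] = []
    for r in range(n_runs):
        seed = base_seed + r
        try:
            res = run_fit(problem, PSOHyperparameters(
                n_particles=hyper.n_particles,
                n_iterations=hyper.n_iterations,
                phi1=hyper.phi1,
                phi2=hyper.phi2,
                gamma=hyper.gamma,
                seed=seed,
            ))
        except Exception as exc:  # noqa: BLE001 - recorded, re-raised if all fail
            failures.append((seed, str(exc)))
            continue
        results.append(res)
        if callback is not None:
            callback(r, res)
    if len(results) < max(1, min(2, n_runs)):
        raise ConfigurationError(
            f"only {len(results)} of {n_runs} runs succeeded: {failures}"
        )
    mask = problem.fit_mask
    params = np.array([res.best_params[mask] for res in results])
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        if truth.size == problem.model.n_parameters:
            truth = truth[mask]
    return RepeatedFitResult(
        model_name=problem.model.name,
        parameter_names=problem.fitted_names,
        params=params,
        errors=np.array([res.best_error for res in results]),
        lower=problem.fitted_lower,
        upper=problem.fitted_upper,
        base_seed=base_seed,
        truth=truth,
        failures=failures,
    )


def _check_rosters(a: RepeatedFitResult, b: RepeatedFitResult) -> None:
    if a.parameter_names != b.parameter_names:
        raise ConfigurationError(
            "repeated-fit results cover different parameter rosters: "
            f"{a.parameter_names} vs {b.parameter_names}"
        )


def sd_reduction_count(a: RepeatedFitResult, b: RepeatedFitResult) -> int:
    """How many fitted parameters have a smaller SD in ``b`` than in ``a``."""
    _check_rosters(a, b)
    if a.n_runs < 2 or b.n_runs < 2:
        raise ConfigurationError("SD comparison requires at least two runs per side")
    sd_a = a.params.std(axis=0, ddof=1)
    sd_b = b.params.std(axis=0, ddof=1)
    return int(np.sum(sd_b < sd_a))


def pairwise_parameter_tests(
    a: RepeatedFitResult,
    b: RepeatedFitResult,
    alpha_strict: float = 0.001,
    alpha_loose: float = 0.01,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-parameter two-sample t-tests between two repeated-fit ensembles.

    Returns a frame with the t statistic, p-value and a three-way verdict:
    ``different`` (p < alpha_strict), ``borderline`` (alpha_strict <= p <
    alpha_loose) or ``not-different``.  Parameters with zero variance in
    both groups and equal means are ``not-different`` by convention.
    """
    _check_rosters(a, b)
    if not 0 < alpha_strict < alpha_loose < 1:
        raise ConfigurationError("need 0 < alpha_strict < alpha_loose < 1")
    rows = []
    for j, name in enumerate(a.parameter_names):
        x = a.params[:, j]
        y = b.params[:, j]
        if x.std() == 0.0 and y.std() == 0.0:
            t, p = (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=not welch)
        if p < alpha_strict:
            verdict = "different"
        elif p < alpha_loose:
            verdict = "borderline"
        else:
            verdict = "not-different"
        rows.append((name, float(t), float(p), verdict))
    return pd.DataFrame(rows, columns=["parameter", "t", "p", "verdict"])
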