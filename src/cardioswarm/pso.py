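"""Constriction-coefficient particle swarm optimization of model parameters.

Each particle carries a position p (one value per fitted parameter) and a
velocity v, updated each iteration as

    v <- chi * [ v + u(0, phi1) (.) (b_i - p) + u(0, phi2) (.) (b - p) ]
    p <- p + gamma * v

where b_i is the particle's personal best position, b the global best,
u(0, phi) a vector of uniform draws in [0, phi), (.) the elementwise
product, chi = 2 / (phi - 2 + sqrt(phi^2 - 4 phi)) with phi = phi1 + phi2
the Clerc constriction coefficient, and gamma a learning rate damping the
position update.  Defaults: phi1 = phi2 = 2.05 (chi ~ 0.73), gamma = 0.05.

Positions are initialized uniformly inside the per-parameter bounds and
velocities at zero.  After each move, any coordinate outside its bounds is
resolved by redrawing it uniformly from the three-quarters of the range
adjacent to the violated bound; the velocity component is left untouched
and no other coordinate of the particle changes.  Termination is after a
fixed number of iterations.  A single seeded generator drives
initialization and all updates, so identical seeds reproduce a run
bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as _models
from .errors import ConfigurationError
from .fitness import WORST_FITNESS, DatasetEntry, batch_dataset_error
from .simulate import PacingProtocol, StimulusSpec, Trace, integrate_batch

__all__ = [
    "PSOHyperparameters",
    "FitProblem",
    "SwarmState",
    "FitResult",
    "constriction_coefficient",
    "init_swarm",
    "update_swarm",
    "optimize",
    "run_fit",
    "save_run_details",
]


def constriction_coefficient(phi1: float, phi2: float) -> float:
    """Clerc constriction chi = 2/(phi - 2 + sqrt(phi^2 - 4 phi)), phi = phi1 + phi2."""
    phi = phi1 + phi2
    if phi <= 4.0:
        raise ConfigurationError(
            f"constriction requires phi1 + phi2 > 4, got {phi}"
        )
    return 2.0 / (phi - 2.0 + math.sqrt(phi * phi - 4.0 * phi))


@dataclass(frozen=True)
class PSOHyperparameters:
    n_particles: int = 1024
    n_iterations: int = 32
    phi1: float = 2.05
    phi2: float = 2.05
    gamma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 0:
            raise ConfigurationError("need n_particles >= 1 and n_iterations >= 0")
        if self.gamma <= 0:
            raise ConfigurationError("learning rate gamma must be positive")
        constriction_coefficient(self.phi1, self.phi2)  # validates phi1 + phi2

    @property
    def chi(self) -> float:
        return constriction_coefficient(self.phi1, self.phi2)


@dataclass
class FitProblem:
    """Datasets, model, bounds and protocol settings defining one fit.

    ``fit_mask`` selects the fitted parameters; the remaining entries of
    ``fixed_values`` are held at their given values.  Bounds apply to the
    fitted parameters only (rows of ``lower``/``upper`` are full length for
    simplicity).  All datasets share the stimulus settings, beat counts and
    sample interval; the cycle length varies per dataset.
    """

    model: _models.ModelSpec
    entries: list[DatasetEntry]
    n_stimuli: int
    n_prerecording: int = 0
    dt: float = 0.02
    sample_interval: float = 1.0
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    fit_mask: np.ndarray | None = None
    fixed_values: np.ndarray | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        if isinstance(self.model, str):
            self.model = _models.get_model(self.model)
        if not self.entries:
            raise ConfigurationError("a fit needs at least one dataset")
        n = self.model.n_parameters
        self.fit_mask = (
            np.ones(n, dtype=bool)
            if self.fit_mask is None
            else np.asarray(self.fit_mask, dtype=bool)
        )
        if self.fit_mask.shape != (n,):
            raise ConfigurationError(f"fit_mask must have length {n}")
        if not self.fit_mask.any():
            raise ConfigurationError("at least one parameter must be fitted")
        self.fixed_values = (
            self.model.defaults
            if self.fixed_values is None
            else np.asarray(self.fixed_values, dtype=float)
        )
        self.lower = self.model.lower if self.lower is None else np.asarray(self.lower, float)
        self.upper = self.model.upper if self.upper is None else np.asarray(self.upper, float)
        if np.any(self.lower[self.fit_mask] >= self.upper[self.fit_mask]):
            raise ConfigurationError("each fitted parameter needs lower < upper")
        for e in self.entries:
            if e.kind == "apd" and len(e.apd_values) != self.n_stimuli:
                raise ConfigurationError(
                    f"APD dataset at CL {e.cycle_length} ms provides "
                    f"{len(e.apd_values)} APDs but n_stimuli is {self.n_stimuli}"
                )

    @property
    def n_fitted(self) -> int:
        return int(self.fit_mask.sum())

    @property
    def fitted_names(self) -> list[str]:
        return [n for n, m in zip(self.model.parameter_names, self.fit_mask) if m]

    @property
    def fitted_lower(self) -> np.ndarray:
        return self.lower[self.fit_mask]

    @property
    def fitted_upper(self) -> np.ndarray:
        return self.upper[self.fit_mask]

    def protocol_for(self, entry: DatasetEntry) -> PacingProtocol:
        return PacingProtocol(
            cycle_length=entry.cycle_length,
            n_stimuli=self.n_stimuli,
            n_prerecording=self.n_prerecording,
            dt=self.dt,
            sample_interval=self.sample_interval,
            stimulus=self.stimulus,
        )

    def assemble(self, positions: np.ndarray) -> np.ndarray:
        """Expand (P, n_fitted) positions into full parameter rows."""
        positions = np.atleast_2d(positions)
        full = np.tile(self.fixed_values, (positions.shape[0], 1))
        full[:, self.fit_mask] = positions
        return full

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        """Composite fitness of each position (rows of (P, n_fitted))."""
        full = self.assemble(positions)
        P = full.shape[0]
        total = np.zeros(P)
        worst = np.zeros(P, dtype=bool)
        for entry in self.entries:
            batch = integrate_batch(self.model, full, self.protocol_for(entry))
            err = batch_dataset_error(
                batch.values, batch.valid, entry, self.sample_interval
            )
            bad = err >= WORST_FITNESS
            worst |= bad
            total += np.where(bad, 0.0, entry.weight * err)
        total[worst] = WORST_FITNESS
        return total

    def simulate_best(self, params_full: np.ndarray) -> list[Trace]:
        """Model traces of one parameter vector under each dataset's protocol."""
        out = []
        for entry in self.entries:
            batch = integrate_batch(
                self.model, np.atleast_2d(params_full), self.protocol_for(entry)
            )
            out.append(batch[0])
        return out


@dataclass
class SwarmState:
    positions: np.ndarray  # (P, d)
    velocities: np.ndarray  # (P, d)
    errors: np.ndarray  # (P,) fitness at current positions
    best_positions: np.ndarray  # (P, d) personal bests
    best_errors: np.ndarray  # (P,)
    global_best: np.ndarray  # (d,)
    global_best_error: float
    iteration: int = 0
    error_history: list[float] = field(default_factory=list)


def init_swarm(
    problem: FitProblem,
    hyper: PSOHyperparameters,
    rng: np.random.Generator | None = None,
    objective=None,
) -> SwarmState:
    """Uniform random positions within bounds, zero velocities, evaluated."""
    rng = np.random.default_rng(hyper.seed) if rng is None else rng
    lower = problem.fitted_lower
    upper = problem.fitted_upper
    d = lower.size
    P = hyper.n_particles
    positions = rng.uniform(lower, upper, size=(P, d))
    objective = problem.evaluate if objective is None else objective
    errors = np.asarray(objective(positions), dtype=float)
    best = int(np.argmin(errors))
    state = SwarmState(
        positions=positions,
        velocities=np.zeros((P, d)),
        errors=errors,
        best_positions=positions.copy(),
        best_errors=errors.copy(),
        global_best=positions[best].copy(),
        global_best_error=float(errors[best]),
    )
    state.error_history.append(state.global_best_error)
    return state


def _reset_out_of_bounds(
    positions: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw out-of-range coordinates within the nearest 3/4 of the range."""
    span = 0.75 * (upper - lower)
    below = positions < lower
    above = positions > upper
    if below.any():
        draw = lower + rng.uniform(size=positions.shape) * span
        positions = np.where(below, draw, positions)
    if above.any():
        draw = upper - rng.uniform(size=positions.shape) * span
        positions = np.where(above, draw, positions)
    return positions


def update_swarm(
    state: SwarmState,
    hyper: PSOHyperparameters,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
    objective,
) -> SwarmState:
    """One velocity/position update, evaluation, and best-tracking pass."""
    P, d = state.positions.shape
    u1 = rng.uniform(0.0, hyper.phi1, size=(P, d))
    u2 = rng.uniform(0.0, hyper.phi2, size=(P, d))
    chi = hyper.chi
    state.velocities = chi * (
        state.velocities
        + u1 * (state.best_positions - state.positions)
        + u2 * (state.global_best - state.positions)
    )
    state.positions = state.positions + hyper.gamma * state.velocities
    state.positions = _reset_out_of_bounds(state.positions, lower, upper, rng)
    state.errors = np.asarray(objective(state.positions), dtype=float)
    improved = state.errors < state.best_errors  # ties keep the incumbent
    state.best_positions[improved] = state.positions[improved]
    state.best_errors[improved] = state.errors[improved]
    best = int(np.argmin(state.best_errors))
    if state.best_errors[best] < state.global_best_error:
        state.global_best = state.best_positions[best].copy()
        state.global_best_error = float(state.best_errors[best])
    state.iteration += 1
    state.error_history.append(state.global_best_error)
    return state


def optimize(
    objective,
    lower: np.ndarray,
    upper: np.ndarray,
    hyper: PSOHyperparameters,
    callback=None,
) -> SwarmState:
    """Minimize an arbitrary batch objective over a box (generic PSO core)."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)

    class _Box:  # minimal problem shim for init_swarm
        fitted_lower = lower
        fitted_upper = upper
        evaluate = staticmethod(objective)

    rng = np.random.default_rng(hyper.seed)
    state = init_swarm(_Box, hyper, rng=rng, objective=objective)
    for _ in range(hyper.n_iterations):
        update_swarm(state, hyper, lower, upper, rng, objective)
        if callback is not None:
            callback(state)
    return state


@dataclass
class FitResult:
    """Outcome of one swarm fit: best parameters, error and convergence."""

    model_name: str
    parameter_names: list[str]
    fitted_names: list[str]
    best_params: np.ndarray  # full parameter vector
    best_error: float
    error_history: np.ndarray
    seed: int
    hyper: PSOHyperparameters
    best_traces: list[Trace] = field(default_factory=list, repr=False)
    n_invalid_final: int = 0

    @property
    def best_params_dict(self) -> dict[str, float]:
        return dict(zip(self.parameter_names, map(float, self.best_params)))


def run_fit(
    problem: FitProblem,
    hyper: PSOHyperparameters,
    callback=None,
) -> FitResult:
    """Initialize and iterate the swarm on a fitting problem."""
    rng = np.random.default_rng(hyper.seed)
    state = init_swarm(problem, hyper, rng=rng)
    lower = problem.fitted_lower
    upper = problem.fitted_upper
    for _ in range(hyper.n_iterations):
        update_swarm(state, hyper, lower, upper, rng, problem.evaluate)
        if callback is not None:
            callback(state)
    if state.global_best_error >= WORST_FITNESS:
        raise ConfigurationError(
            "no particle produced a valid comparison in any iteration; "
            "check bounds, stimulus settings and dataset normalization"
        )
    best_full = problem.assemble(state.global_best[None, :])[0]
    return FitResult(
        model_name=problem.model.name,
        parameter_names=list(problem.model.parameter_names),
        fitted_names=problem.fitted_names,
        best_params=best_full,
        best_error=state.global_best_error,
        error_history=np.asarray(state.error_history),
        seed=hyper.seed,
        hyper=hyper,
        best_traces=problem.simulate_best(best_full),
        n_invalid_final=int(np.sum(state.errors >= WORST_FITNESS)),
    )


def save_run_details(
    result: FitResult,
    problem: FitProblem,
    path: str,
    csv_path: str | None = None,
) -> None:
    """Full-precision run record (JSON) and optional parameter CSV."""
    details = {
        "model": result.model_name,
        "seed": result.seed,
        "hyperparameters": {
            "n_particles": result.hyper.n_particles,
            "n_iterations": result.hyper.n_iterations,
            "phi1": result.hyper.phi1,
            "phi2": result.hyper.phi2,
            "chi": result.hyper.chi,
            "gamma": result.hyper.gamma,
        },
        "protocol": {
            "n_stimuli": problem.n_stimuli,
            "n_prerecording": problem.n_prerecording,
            "dt": problem.dt,
            "sample_interval": problem.sample_interval,
            "stimulus": {
                "shape": problem.stimulus.shape,
                "magnitude": problem.stimulus.magnitude,
                "duration": problem.stimulus.duration,
            },
        },
        "datasets": [
            {
                "kind": e.kind,
                "cycle_length": e.cycle_length,
                "weight": e.weight,
                "label": e.label,
                "n_samples": int(e.n_samples) if e.kind == "voltage" else len(e.apd_values),
            }
            for e in problem.entries
        ],
        "fit_mask": problem.fit_mask.astype(int).tolist(),
        "fixed_values": problem.fixed_values.tolist(),
        "lower": problem.lower.tolist(),
        "upper": problem.upper.tolist(),
        "best_error": result.best_error,
        "best_parameters": result.best_params_dict,
        "error_history": result.error_history.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(details, fh, indent=1)
    if csv_path is not None:
        pd.DataFrame(
            {
                "name": result.parameter_names,
                "value": result.best_params,
                "fitted": problem.fit_mask.astype(bool),
            }
        ).to_csv(csv_path, index=False)
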