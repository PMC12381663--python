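"""Constriction coefficient, swarm updates, bounds handling, determinism."""

import math

import numpy as np
import pytest

from cardioswarm import (
    ConfigurationError,
    DatasetEntry,
    FitProblem,
    PSOHyperparameters,
    constriction_coefficient,
    get_model,
    optimize,
    run_fit,
)
from cardioswarm.pso import SwarmState, _reset_out_of_bounds, update_swarm
from cardioswarm.simulate import PacingProtocol, integrate
from cardioswarm.synthdata import SyntheticDatasetSpec, generate


class TestConstriction:
    def test_default_hyperparameters(self):
        chi = constriction_coefficient(2.05, 2.05)
        assert chi == pytest.approx(2.0 / (2.1 + math.sqrt(4.1**2 - 4 * 4.1)))
        assert round(chi, 2) == 0.73

    def test_closed_form_example(self):
        assert constriction_coefficient(3.0, 3.0) == pytest.approx(
            2.0 / (4.0 + math.sqrt(12.0))
        )

    def test_boundary_limit(self):
        # chi -> 1 as phi -> 4 from above
        assert constriction_coefficient(2.0, 2.0 + 1e-10) == pytest.approx(1.0, abs=1e-4)
        with pytest.raises(ConfigurationError):
            constriction_coefficient(2.0, 2.0)


QUAD_C = np.array([1.0, -2.0, 0.5, 3.0])


def quad(X):
    return np.sum((np.atleast_2d(X) - QUAD_C) ** 2, axis=1)


class TestSwarmCore:
    def test_init_positions_within_bounds_many_seeds(self):
        lower = np.array([-1.0, 0.0, 10.0])
        upper = np.array([1.0, 5.0, 11.0])
        for seed in range(5):
            st = optimize(
                lambda X: np.sum(X**2, axis=1),
                lower,
                upper,
                PSOHyperparameters(n_particles=64, n_iterations=0, seed=seed),
            )
            assert np.all(st.positions >= lower) and np.all(st.positions <= upper)

    def test_degenerate_range(self):
        eps = 1e-9
        st = optimize(
            lambda X: np.sum(X, axis=1),
            np.array([2.0]),
            np.array([2.0 + eps]),
            PSOHyperparameters(n_particles=16, n_iterations=5, seed=0),
        )
        assert np.all(np.abs(st.positions - 2.0) <= eps)

    def test_same_seed_identical_swarms(self):
        hyper = PSOHyperparameters(n_particles=32, n_iterations=20, seed=11)
        a = optimize(quad, -5 * np.ones(4), 5 * np.ones(4), hyper)
        b = optimize(quad, -5 * np.ones(4), 5 * np.ones(4), hyper)
        assert np.array_equal(a.positions, b.positions)
        assert a.error_history == b.error_history

    def test_converged_particle_is_fixed_point(self):
        # at the global best with zero velocity, the update leaves the
        # particle in place
        pos = QUAD_C[None, :].copy()
        state = SwarmState(
            positions=pos.copy(),
            velocities=np.zeros((1, 4)),
            errors=quad(pos),
            best_positions=pos.copy(),
            best_errors=quad(pos),
            global_best=QUAD_C.copy(),
            global_best_error=0.0,
        )
        hyper = PSOHyperparameters(n_particles=1, n_iterations=1, seed=0)
        rng = np.random.default_rng(0)
        update_swarm(state, hyper, -5 * np.ones(4), 5 * np.ones(4), rng, quad)
        assert np.array_equal(state.positions, QUAD_C[None, :])
        assert np.all(state.velocities == 0.0)

    def test_bounds_reset_rule(self):
        lower = np.array([0.0])
        upper = np.array([8.0])  # range 8 -> nearest three-quarters spans 6
        rng = np.random.default_rng(5)
        below = np.full((4000, 1), -3.0)
        reset = _reset_out_of_bounds(below.copy(), lower, upper, rng)
        assert reset.min() >= 0.0 and reset.max() <= 6.0
        assert reset.max() > 5.5 and reset.min() < 0.5  # spans the subrange
        above = np.full((4000, 1), 9.5)
        reset = _reset_out_of_bounds(above.copy(), lower, upper, rng)
        assert reset.min() >= 2.0 and reset.max() <= 8.0
        assert reset.min() < 2.5 and reset.max() > 7.5

    def test_quadratic_toy_convergence(self):
        st = optimize(
            quad,
            -5 * np.ones(4),
            5 * np.ones(4),
            PSOHyperparameters(n_particles=128, n_iterations=200, seed=0),
        )
        assert np.abs(st.positions.mean(axis=0) - QUAD_C).max() < 1e-3
        assert st.global_best_error < 1e-10

    def test_single_particle_single_iteration(self):
        st = optimize(
            quad,
            -5 * np.ones(4),
            5 * np.ones(4),
            PSOHyperparameters(n_particles=1, n_iterations=1, seed=2),
        )
        assert len(st.error_history) == 2
        assert st.global_best_error == pytest.approx(quad(st.global_best)[0])

    def test_error_history_non_increasing(self):
        st = optimize(
            quad,
            -5 * np.ones(4),
            5 * np.ones(4),
            PSOHyperparameters(n_particles=32, n_iterations=60, seed=4),
        )
        hist = np.asarray(st.error_history)
        assert np.all(np.diff(hist) <= 0.0)


@pytest.fixture(scope="module")
def small_ms_problem():
    recs = generate(
        SyntheticDatasetSpec(model="MS", cycle_lengths=(400.0,), n_recorded_stimuli=1, dt=0.2)
    )
    entries = [DatasetEntry.from_trace(r.trace) for r in recs]
    return FitProblem(
        model="MS", entries=entries, n_stimuli=1, n_prerecording=3, dt=0.2
    )


class TestRunFit:
    def test_fit_problem_validation(self, small_ms_problem):
        with pytest.raises(ConfigurationError, match="at least one parameter"):
            FitProblem(
                model="MS",
                entries=small_ms_problem.entries,
                n_stimuli=1,
                fit_mask=np.zeros(5, dtype=bool),
            )
        with pytest.raises(ConfigurationError, match="APD dataset"):
            FitProblem(
                model="MS",
                entries=[
                    DatasetEntry(kind="apd", cycle_length=400.0, apd_values=[200.0])
                ],
                n_stimuli=2,
            )

    def test_run_fit_reproducible_and_monotone(self, small_ms_problem):
        hyper = PSOHyperparameters(n_particles=48, n_iterations=12, seed=9)
        in_bounds = []

        def check(state):
            in_bounds.append(
                np.all(state.positions >= small_ms_problem.fitted_lower)
                and np.all(state.positions <= small_ms_problem.fitted_upper)
            )

        a = run_fit(small_ms_problem, hyper, callback=check)
        b = run_fit(small_ms_problem, hyper)
        assert np.array_equal(a.best_params, b.best_params)
        assert np.array_equal(a.error_history, b.error_history)
        assert all(in_bounds)
        assert np.all(np.diff(a.error_history) <= 0.0)
        assert a.best_error < 0.05  # a short swarm already fits loosely

    def test_fixed_parameters_stay_fixed(self, small_ms_problem):
        spec = get_model("MS")
        mask = np.array([True, True, False, False, True])
        problem = FitProblem(
            model="MS",
            entries=small_ms_problem.entries,
            n_stimuli=1,
            n_prerecording=3,
            dt=0.2,
            fit_mask=mask,
        )
        res = run_fit(problem, PSOHyperparameters(n_particles=32, n_iterations=5, seed=0))
        np.testing.assert_array_equal(res.best_params[~mask], spec.defaults[~mask])
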