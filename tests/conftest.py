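import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.integrate import solve_ivp

from cardioswarm import PacingProtocol, StimulusSpec, models

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def reference_trace(
    model_name: str,
    params,
    cycle_length: float,
    n_beats: int,
    stimulus: StimulusSpec | None = None,
    sample_interval: float = 1.0,
) -> np.ndarray:
    """High-accuracy ODE solution sampled like the Euler integrator.

    Integrates the model's reference right-hand side with an adaptive
    high-order Runge-Kutta method (DOP853, rtol 1e-10), restarting at the
    stimulus on/off discontinuities so the stepper never straddles them.
    Independent of the compiled forward-Euler kernels.
    """
    stimulus = stimulus or StimulusSpec()
    spec = models.get_model(model_name)
    state = models.rest_state(spec, params)
    samples: list[float] = []
    for beat in range(n_beats):
        for t0, t1, s in (
            (0.0, stimulus.duration, stimulus.magnitude),
            (stimulus.duration, cycle_length, 0.0),
        ):
            g0, g1 = beat * cycle_length + t0, beat * cycle_length + t1

            def rhs(t, y, s=s):
                return models.model_rhs(spec, y, params, s)

            first = np.ceil(g0 / sample_interval) * sample_interval
            t_eval = np.arange(first, g1 - 1e-9, sample_interval) - beat * cycle_length
            sol = solve_ivp(
                rhs,
                (t0, t1),
                state,
                method="DOP853",
                rtol=1e-10,
                atol=1e-12,
                max_step=1.0,
                t_eval=np.append(t_eval, t1),
            )
            samples.extend(sol.y[0][:-1])
            state = sol.y[:, -1]
    return np.asarray(samples)


@pytest.fixture(scope="session")
def default_protocol():
    return PacingProtocol(cycle_length=500.0, n_stimuli=2, n_prerecording=2, dt=0.05)
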