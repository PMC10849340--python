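import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ode_oracle():
    """Adaptive high-accuracy ODE integration of the two-state system."""
    from scipy.integrate import solve_ivp

    def solve(params, times):
        def rhs(_t, y):
            return [
                (params.g_wt - params.r) * y[0],
                params.g_mut * y[1] + params.r * y[0],
            ]

        times = np.atleast_1d(np.asarray(times, dtype=float))
        sol = solve_ivp(
            rhs,
            (0.0, float(times.max()) if len(times) else 0.0),
            [params.p_wt0, params.p_mut0],
            t_eval=times,
            method="DOP853",
            rtol=1e-12,
            atol=1e-14,
        )
        assert sol.success
        return sol.y[0], sol.y[1]

    return solve
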