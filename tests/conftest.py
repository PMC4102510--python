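import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bapkin.exposure import ExposureScenario, ExposureWindow
from bapkin.params import default_human_pbpk_params, default_tk_params
from bapkin.pbpk import PBPKModel

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_human_pbpk_params()


@pytest.fixture(scope="session")
def tk():
    return default_tk_params()


@pytest.fixture(scope="session")
def model(params):
    return PBPKModel(params)


@pytest.fixture(scope="session")
def inhalation_8h():
    return ExposureScenario(
        (ExposureWindow("inhalation", 8.0, 16.0, 1000.0),), 168.0, "inh-8h")


@pytest.fixture(scope="session")
def dermal_8h():
    return ExposureScenario(
        (ExposureWindow("dermal", 8.0, 16.0, 50.0),), 168.0, "dermal-8h")


@pytest.fixture(scope="session")
def multiroute_week():
    """Seven-day scenario with five windows across both main routes."""
    windows = tuple(
        [ExposureWindow("inhalation", 8 + 24 * d, 16 + 24 * d, 500.0)
         for d in range(3)]
        + [ExposureWindow("dermal", 8 + 24 * d, 20 + 24 * d, 30.0)
           for d in (3, 4)])
    return ExposureScenario(windows, 168.0, "week-5-windows")


def piecewise_ode_solution(model, scenario, t_eval, rtol=1e-10, atol=1e-13):
    """Independent adaptive-ODE solution of the PBPK vector field.

    Integrates segment-by-segment between exposure breakpoints with scipy's
    BDF so input discontinuities never sit inside an integration span.
    """
    from scipy.integrate import solve_ivp

    from bapkin.pbpk import N_STATES

    t_eval = np.asarray(t_eval, dtype=float)
    edges = scenario.breakpoints()
    edges = edges[(edges >= t_eval[0]) & (edges <= t_eval[-1])]
    edges = np.union1d(edges, [t_eval[0], t_eval[-1]])
    out = np.zeros((len(t_eval), N_STATES))
    x = np.zeros(N_STATES)
    for a, b in zip(edges, edges[1:]):
        keep = (t_eval >= a - 1e-12) & (t_eval <= b + 1e-12)
        ts = np.union1d(t_eval[keep], [a, b])
        sol = solve_ivp(model.derivatives, (a, b), x, t_eval=ts,
                        args=(scenario,), method="BDF", rtol=rtol, atol=atol)
        assert sol.success, sol.message
        for i, t in enumerate(t_eval):
            if keep[i]:
                j = int(np.argmin(np.abs(sol.t - t)))
                out[i] = sol.y[:, j]
        x = sol.y[:, -1]
    return out
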