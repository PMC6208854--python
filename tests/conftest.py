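import dataclasses

import numpy as np
import pytest

from impflow import KineticParams, TimeGrid, render_phantom, simulate_study


@pytest.fixture(scope="session")
def grid():
    """Clinical frame grid: 60 frames of 2 s."""
    return TimeGrid.default()


@pytest.fixture(scope="session")
def params():
    """Physiologic mid-range fixture parameters."""
    return KineticParams()


@pytest.fixture(scope="session")
def microsphere_study(params, grid):
    return simulate_study(params, grid, model="microsphere")


@pytest.fixture(scope="session")
def noiseless_phantom(microsphere_study, params):
    return render_phantom(microsphere_study, params, noise="none")


@pytest.fixture()
def vary():
    """Helper to derive parameter variants from the fixture set."""
    def _vary(base, **kwargs):
        return dataclasses.replace(base, **kwargs)
    return _vary


def ode_oracle(params, grid, refine=10, model="microsphere"):
    """Independent fine-grid integrator for the study kinetics.

    Solves the raw ODE system with scipy's adaptive LSODA at ``refine``×
    temporal refinement — a completely separate code path from the
    closed-form incomplete-gamma solution in the package.
    """
    from scipy.integrate import solve_ivp
    from scipy.stats import gamma as gamma_dist

    b = params.bolus
    E = 1.0 if model == "microsphere" else params.E
    k2 = 0.0 if model == "microsphere" else params.k2

    def cr(t):
        u = t - b.onset_min
        return (params.D / params.P) * gamma_dist.pdf(
            u, a=b.shape, scale=b.scale_min) if u > 0 else 0.0

    def rhs(t, y):
        L, Cb, cum_ca = y
        ca = params.k_lung * L / params.P
        return [params.P * cr(t) - params.k_lung * L,
                E * params.F * params.lambda_lipo * ca - k2 * Cb,
                ca]

    mids = grid.refined(refine).mid_times
    sol = solve_ivp(rhs, (0.0, grid.end_time), [0.0, 0.0, 0.0],
                    t_eval=mids, rtol=1e-10, atol=1e-4, method="LSODA")
    assert sol.success
    return mids, {"L": sol.y[0], "Cb": sol.y[1], "cum_Ca": sol.y[2],
                  "Ca": params.k_lung * sol.y[0] / params.P}
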