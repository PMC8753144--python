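import pytest
from hypothesis import settings

import aeroloft as al

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def profile():
    return al.AtmosphereProfile.embedded()


@pytest.fixture(scope="session")
def gravity():
    return al.GravityModel()


@pytest.fixture(scope="session")
def rk4_velocity():
    """Independent fourth-order integrator for the signed quadratic-drag ODE.

    Classical RK4 on dv/dt = -g + sgn(w - v) * (rho / (rho_p h)) * (w - v)^2
    from rest, written without reference to the closed-form solution it
    cross-checks.
    """

    def solve(particle, rho, g, w, t_end, n_steps=4000, v0=0.0):
        lam = rho / (particle.rho_p * particle.h)

        def f(v):
            rel = w - v
            sign = 1.0 if rel >= 0 else -1.0
            return -g + sign * lam * rel * rel

        dt = t_end / n_steps
        v = v0
        for _ in range(n_steps):
            k1 = f(v)
            k2 = f(v + 0.5 * dt * k1)
            k3 = f(v + 0.5 * dt * k2)
            k4 = f(v + dt * k3)
            v += dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        return v

    return solve
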