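"""Vertical-wind dynamics of a disc particle: the core force balance.

A vertical wind of speed ``w`` (up positive) exerts the stagnation-pressure
drag of the relative flow on a broadside disc with unit drag coefficient,

    F_wind = sgn(w - v) * rho * pi * r^2 * (w - v)^2,

where ``v`` is the particle velocity and the sign factor keeps the force
aligned with the relative wind. Dividing by the particle mass
m = rho_p pi r^2 h gives the equation of motion

    dv/dt = -g + sgn(w - v) * lambda * (w - v)^2,   lambda = rho / (rho_p h).

For a particle starting at rest under a super-threshold upward wind this
Riccati-type equation has a closed-form solution (``transient_velocity``)
that relaxes on the timescale 1/sqrt(lambda g) towards the steady state

    v_ss = w - sqrt(g / lambda) = w - sqrt(g rho_p h / rho).

The wind speed at which v_ss = 0, namely sqrt(g rho_p h / rho), is the
threshold velocity: the minimum updraft that supports the particle's weight,
identically equal to the particle's terminal fall speed relative to the air.

All quantities SI. Air resistance against the particle's own motion beyond
the relative-wind term is neglected, per the directed-flow picture.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .particles import TestParticle

__all__ = [
    "DRAG_COEFFICIENT",
    "DynamicsContext",
    "sign_factor",
    "wind_force",
    "acceleration",
    "transient_velocity",
    "steady_state_velocity",
    "threshold_velocity",
    "relaxation_time",
]

#: Drag coefficient of the broadside disc; fixed at unity by construction.
DRAG_COEFFICIENT = 1.0


def sign_factor(relative_wind: float) -> float:
    """Sign of the relative wind (+1 for w > v, -1 for w < v, +1 at zero).

    The value at exactly zero relative wind is immaterial because the force
    it multiplies vanishes quadratically there.
    """
    return -1.0 if relative_wind < 0 else 1.0


@dataclass(frozen=True)
class DynamicsContext:
    """Derived drag quantities for a particle in given air.

    Attributes
    ----------
    lambda_
        Signed drag parameter H * rho / (rho_p h), units m-1.
    b
        Separable-form parameter lambda_ / g, units s2 m-2.
    H
        Sign factor of the relative wind, +1 or -1.
    g
        Local gravitational acceleration (m s-2).
    rho
        Local air density (kg m-3).
    """

    lambda_: float
    b: float
    H: float
    g: float
    rho: float

    @classmethod
    def for_particle(
        cls, p: TestParticle, rho: float, g: float, w: float, v: float = 0.0
    ) -> "DynamicsContext":
        if rho < 0:
            raise ValueError("air density must be non-negative")
        if g <= 0:
            raise ValueError("gravitational acceleration must be positive")
        h_sign = sign_factor(w - v)
        lam = h_sign * rho / (p.rho_p * p.h)
        return cls(lambda_=lam, b=lam / g, H=h_sign, g=g, rho=rho)


def wind_force(rho: float, r: float, w: float, v: float) -> float:
    """Signed wind force (N, up positive) on a disc of radius ``r``.

    Magnitude is the stagnation-pressure drag rho pi r^2 (w - v)^2 with unit
    drag coefficient; the sign follows the relative wind.
    """
    if rho < 0:
        raise ValueError("air density must be non-negative")
    if r <= 0:
        raise ValueError("disc radius must be positive")
    rel = w - v
    return sign_factor(rel) * DRAG_COEFFICIENT * rho * math.pi * r**2 * rel * rel


def acceleration(
    p: TestParticle, rho: float, g: float, w: float, v: float
) -> float:
    """Net vertical acceleration (m s-2) of the particle: weight plus drag."""
    ctx = DynamicsContext.for_particle(p, rho, g, w, v)
    rel = w - v
    return -g + ctx.lambda_ * rel * rel


def threshold_velocity(p: TestParticle, rho: float, g: float) -> float:
    """Minimum upward wind (m s-1) that balances the particle's weight.

    Equals sqrt(g rho_p h / rho) — the particle's terminal fall speed
    relative to the air. Winds above this threshold produce net ascent.
    """
    if rho <= 0:
        raise ValueError("air density must be positive")
    if g <= 0:
        raise ValueError("gravitational acceleration must be positive")
    return math.sqrt(g * p.column_density / rho)


def steady_state_velocity(p: TestParticle, rho: float, g: float, w: float) -> float:
    """Particle velocity (m s-1, signed) once drag and weight balance.

    Returns w - sqrt(g rho_p h / rho). A negative value is the quasi-steady
    descent rate: the particle falls at its terminal speed relative to the
    (possibly rising) air.
    """
    return w - threshold_velocity(p, rho, g)


def relaxation_time(p: TestParticle, rho: float, g: float) -> float:
    """e-folding timescale (s) for relaxation towards the steady state.

    1 / sqrt(lambda g) with lambda = rho / (rho_p h). For the particles and
    altitudes of interest this is of order a second or less, far shorter than
    the minutes-to-hours over which the observed large vertical winds vary —
    the separation of timescales that justifies the quasi-steady treatment.
    """
    if rho <= 0:
        raise ValueError("air density must be positive")
    if g <= 0:
        raise ValueError("gravitational acceleration must be positive")
    lam = rho / p.column_density
    return 1.0 / math.sqrt(lam * g)


def transient_velocity(
    p: TestParticle, rho: float, g: float, w: float, t: float
) -> float:
    """Closed-form velocity (m s-1) at time ``t`` of a particle from rest.

    Valid for an upward wind above the threshold velocity. Writing
    lambda = rho / (rho_p h) and u* = sqrt(g / lambda) (the threshold), the
    relative velocity u = w - v obeys du/dt = g - lambda u^2 and decays from
    u(0) = w to u* as

        u(t) = u* * [(w + u*) + (w - u*) E] / [(w + u*) - (w - u*) E],
        E    = exp(-2 t sqrt(lambda g)).

    Hence v(0) = 0 and v(t) -> w - u* as t -> infinity, approaching but never
    reaching the wind speed.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    u_star = threshold_velocity(p, rho, g)
    if w <= u_star:
        raise ValueError(
            f"transient solution requires an upward wind above the threshold "
            f"velocity ({u_star:.3g} m/s); got w = {w:.3g} m/s"
        )
    lam = rho / p.column_density
    decay = math.exp(-2.0 * t * math.sqrt(lam * g))
    num = (w + u_star) + (w - u_star) * decay
    den = (w + u_star) - (w - u_star) * decay
    return w - u_star * num / den
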