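"""Altitude integration through a varying-density column, and ceilings.

The integrator advances a particle's altitude through the atmosphere under
piecewise wind forcing. Within each time step the air density, gravity and
wind are frozen (they vary on kilometres and minutes, far slower than the
sub-second velocity relaxation), and the density is re-read from the profile
at the start of every step so multi-kilometre climbs see the exponential
fall-off.

Two modes:

``quasi_steady``
    The particle moves at its steady-state velocity for the local
    conditions each step. Valid when episode durations far exceed the
    relaxation time, which holds for all particles of interest.
``full_ode``
    The signed quadratic-drag equation of motion is integrated with
    classical RK4 sub-stepping inside each step, resolving the transient.

``ceiling_altitude`` solves for the altitude at which the thinning air
raises the threshold velocity to the available wind speed — the highest
altitude a sustained updraft of that speed can carry the particle to.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .atmosphere import AtmosphereProfile, GravityModel, density_at, gravity_at
from .dynamics import (
    relaxation_time,
    sign_factor,
    steady_state_velocity,
    threshold_velocity,
)
from .particles import TestParticle
from .wind import WindEpisode, WindSeries

__all__ = [
    "Trajectory",
    "CeilingResult",
    "ExcursionResult",
    "integrate",
    "ceiling_altitude",
    "horizontal_excursion",
    "mean_ascent_climb",
]

#: Default integration step (s); well below wind variation timescales.
DEFAULT_DT = 1.0
#: Default correlation length (m) of vertical winds along an auroral arc.
DEFAULT_CORRELATION_LENGTH = 3e5

Mode = Literal["quasi_steady", "full_ode"]


@dataclass
class Trajectory:
    """Time-ordered record (t, z, v, w, rho) of an ascent/descent run."""

    times: np.ndarray
    altitudes: np.ndarray
    velocities: np.ndarray
    winds: np.ndarray
    densities: np.ndarray
    mode: Mode
    metadata: dict = field(default_factory=dict)

    @property
    def stop_reason(self) -> str:
        return self.metadata.get("stop_reason", "completed")

    @property
    def climb(self) -> float:
        """Net altitude change (m) over the run."""
        return float(self.altitudes[-1] - self.altitudes[0])

    def to_csv(self, path: str, sidecar: Optional[str] = None) -> None:
        """Write the record as CSV; optionally a JSON metadata sidecar."""
        import pandas as pd

        pd.DataFrame(
            {
                "t_s": self.times,
                "z_m": self.altitudes,
                "v_m_s": self.velocities,
                "w_m_s": self.winds,
                "rho_kg_m3": self.densities,
            }
        ).to_csv(path, index=False, float_format="%.10g")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"mode": self.mode, **self.metadata}, fh, indent=2)
                fh.write("\n")


@dataclass(frozen=True)
class CeilingResult:
    """Outcome of a ceiling solve.

    ``status`` is ``converged`` (altitude is the root, +-1 m), ``above_table``
    (the wind exceeds the threshold everywhere tabulated; altitude is the
    table top, a lower bound), or ``no_ascent`` (the wind is below the
    threshold over the whole searched span; altitude is None).
    """

    altitude: Optional[float]
    status: Literal["converged", "above_table", "no_ascent"]


@dataclass(frozen=True)
class ExcursionResult:
    """Horizontal drift during a climb, checked against a correlation length."""

    distance: float
    within_correlation: bool
    correlation_length: float


def _segments(
    forcing: Union[Sequence[WindEpisode], WindSeries]
) -> list[tuple[float, float, Optional[float]]]:
    """Normalize forcing to (w, duration, rho_override) segments."""
    if isinstance(forcing, WindSeries):
        dt = forcing.dt
        return [(float(w), dt, None) for w in forcing.winds]
    segs = []
    for ep in forcing:
        segs.append((ep.w, ep.duration, ep.rho_override))
    if not segs:
        raise ValueError("forcing must contain at least one episode")
    return segs


def _rk4_step(
    z: float, v: float, w: float, lam_mag: float, g: float, dt: float
) -> tuple[float, float]:
    """One classical RK4 step of (dz/dt, dv/dt) = (v, -g + H lam (w-v)^2)."""

    def dv(vel: float) -> float:
        rel = w - vel
        return -g + sign_factor(rel) * lam_mag * rel * rel

    k1v = dv(v)
    k1z = v
    k2v = dv(v + 0.5 * dt * k1v)
    k2z = v + 0.5 * dt * k1v
    k3v = dv(v + 0.5 * dt * k2v)
    k3z = v + 0.5 * dt * k2v
    k4v = dv(v + dt * k3v)
    k4z = v + dt * k3v
    return (
        z + dt * (k1z + 2 * k2z + 2 * k3z + k4z) / 6.0,
        v + dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0,
    )


def integrate(
    p: TestParticle,
    forcing: Union[Sequence[WindEpisode], WindSeries],
    profile: AtmosphereProfile,
    gravity: GravityModel,
    z0: float,
    dt: float = DEFAULT_DT,
    mode: Mode = "quasi_steady",
    v0: float = 0.0,
) -> Trajectory:
    """Integrate the particle's altitude under piecewise wind forcing.

    Starts at altitude ``z0`` (must lie in the profile's span) and runs until
    the forcing is exhausted or the altitude leaves the tabulated span, in
    which case the trajectory is truncated at the last in-span state and the
    stop reason is recorded in the metadata (``below_table``/``above_table``)
    rather than raising.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mode not in ("quasi_steady", "full_ode"):
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = profile.span
    if not (lo <= z0 <= hi):
        raise ValueError(f"z0 = {z0:g} m outside table span [{lo:g}, {hi:g}] m")

    segs = _segments(forcing)
    times = [0.0]
    alts = [float(z0)]
    winds = []
    rhos = []
    vels = []
    z = float(z0)
    v = float(v0)
    t = 0.0
    stop_reason = "completed"

    def local_rho(z_now: float, override: Optional[float]) -> float:
        return override if override is not None else density_at(profile, z_now)

    done = False
    for w, seg_duration, rho_override in segs:
        if done:
            break
        remaining = seg_duration
        while remaining > 1e-12 * seg_duration:
            step = min(dt, remaining)
            rho = local_rho(z, rho_override)
            g = gravity_at(gravity, z)
            if mode == "quasi_steady":
                v = steady_state_velocity(p, rho, g, w)
                z_new = z + v * step
            else:
                tau = relaxation_time(p, rho, g)
                n_sub = max(1, min(2000, math.ceil(step / (0.05 * tau))))
                sub = step / n_sub
                lam_mag = rho / p.column_density
                z_new, v_new = z, v
                for _ in range(n_sub):
                    z_new, v_new = _rk4_step(z_new, v_new, w, lam_mag, g, sub)
                v = v_new
            vels.append(v)
            winds.append(w)
            rhos.append(rho)
            if z_new < lo or z_new > hi:
                # truncate at the span boundary crossing
                bound = lo if z_new < lo else hi
                frac = (bound - z) / (z_new - z) if z_new != z else 0.0
                t += step * frac
                z = bound
                times.append(t)
                alts.append(z)
                stop_reason = "below_table" if bound == lo else "above_table"
                done = True
                break
            t += step
            z = z_new
            remaining -= step
            times.append(t)
            alts.append(z)

    # state columns describe the step starting at each time; close the final
    # row with the last step's context so all columns have equal length
    winds.append(winds[-1])
    rhos.append(local_rho(z, segs[-1][2]) if stop_reason == "completed" else rhos[-1])
    if mode == "quasi_steady":
        vels.append(
            steady_state_velocity(p, rhos[-1], gravity_at(gravity, z), winds[-1])
        )
    else:
        vels.append(v)

    return Trajectory(
        times=np.asarray(times),
        altitudes=np.asarray(alts),
        velocities=np.asarray(vels),
        winds=np.asarray(winds),
        densities=np.asarray(rhos),
        mode=mode,
        metadata={
            "particle": p.label or "custom",
            "atmosphere": profile.source_label,
            "stop_reason": stop_reason,
        },
    )


def ceiling_altitude(
    p: TestParticle,
    w: float,
    profile: AtmosphereProfile,
    gravity: GravityModel,
    z_min: float = 70e3,
) -> CeilingResult:
    """Altitude at which the threshold velocity rises to meet the wind ``w``.

    Searches the monotone segment of the profile above ``z_min``, where
    density decays with altitude and the threshold therefore grows. The root
    is bracketed on the table grid and refined by Brent's method to 1 m.
    """
    if w <= 0:
        raise ValueError("wind speed must be positive")
    lo, hi = profile.span
    z_min = max(z_min, lo)
    grid = profile.altitudes[profile.altitudes >= z_min]
    if grid.size < 2:
        raise ValueError("search span contains fewer than two table nodes")

    def excess(z: float) -> float:
        return threshold_velocity(
            p, density_at(profile, z), gravity_at(gravity, z)
        ) - w

    if excess(float(grid[0])) >= 0:
        return CeilingResult(altitude=None, status="no_ascent")
    if excess(float(grid[-1])) < 0:
        return CeilingResult(altitude=float(grid[-1]), status="above_table")
    values = np.array([excess(float(z)) for z in grid])
    idx = int(np.argmax(values >= 0))
    root = brentq(excess, float(grid[idx - 1]), float(grid[idx]), xtol=0.5)
    return CeilingResult(altitude=float(root), status="converged")


def horizontal_excursion(
    u: float,
    duration: float,
    correlation_length: float = DEFAULT_CORRELATION_LENGTH,
) -> ExcursionResult:
    """Horizontal drift u*duration (m) and whether it stays within the
    correlation length of the vertical-wind structure (boundary counts as
    within)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    distance = u * duration
    return ExcursionResult(
        distance=distance,
        within_correlation=abs(distance) <= correlation_length,
        correlation_length=correlation_length,
    )


def mean_ascent_climb(mean_velocity: float, duration: float) -> float:
    """Climb (m) from a stated mean ascent speed sustained for ``duration`` s.

    The observed winds grow to their maximum over tens of minutes, so a
    particle's mean ascent over a growth period is a fraction of its peak
    steady-state value; this helper makes that back-of-envelope explicit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    return mean_velocity * duration
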