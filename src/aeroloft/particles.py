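"""Disc-shaped test particles.

A test particle is a rigid disc of radius ``r`` and thickness ``h`` that
always sits broadside to the vertical wind (drag coefficient fixed at unity),
so its bulk density is rho_p = m / (pi r^2 h). Constructors accept any three
of (m, r, h, rho_p) and derive the fourth; the stored quadruple is always
mutually consistent.

Three archetypes used throughout the worked estimates are available as
presets:

``standard_dust``
    A nanometre-scale dust grain: rho_p = 1000 kg m-3, r = h = 1 nm,
    m ~ 3e-24 kg.
``h1n1_virus``
    A virus-sized particle built from the H1N1 virion mass of 0.8 fg and
    size of 109 nm. Both the radius and the thickness of the disc are set
    to 109 nm; that convention is what yields the quoted bulk density of
    ~196 kg m-3 from the 0.8 fg mass, and the preset keeps it.
``bacterial_organelle``
    A small bacterium / organelle fragment: rho_p = 2000 kg m-3, r = 2 um,
    h = 40 nm, m ~ 1e-15 kg.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TestParticle",
    "particle_from_mass",
    "particle_from_density",
    "preset",
    "PRESET_NAMES",
]

_CONSISTENCY_RTOL = 1e-12


@dataclass(frozen=True)
class TestParticle:
    """A disc particle: radius, thickness, bulk density and mass (SI units)."""

    r: float
    h: float
    rho_p: float
    m: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("r", "h", "rho_p", "m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        implied = self.rho_p * math.pi * self.r**2 * self.h
        if abs(implied - self.m) > _CONSISTENCY_RTOL * self.m:
            raise ValueError(
                "inconsistent particle: m = {:.6e} kg but rho_p*pi*r^2*h = "
                "{:.6e} kg".format(self.m, implied)
            )

    @property
    def column_density(self) -> float:
        """rho_p * h (kg m-2): the mass per unit disc area.

        This is the only particle property the threshold and steady-state
        velocities depend on.
        """
        return self.rho_p * self.h


def particle_from_mass(m: float, r: float, h: float, label: str = "") -> TestParticle:
    """Build a disc from its mass and dimensions; bulk density is derived."""
    if m <= 0 or r <= 0 or h <= 0:
        raise ValueError("m, r and h must all be positive")
    rho_p = m / (math.pi * r**2 * h)
    return TestParticle(r=r, h=h, rho_p=rho_p, m=m, label=label)


def particle_from_density(
    rho_p: float, r: float, h: float, label: str = ""
) -> TestParticle:
    """Build a disc from its bulk density and dimensions; mass is derived."""
    if rho_p <= 0 or r <= 0 or h <= 0:
        raise ValueError("rho_p, r and h must all be positive")
    m = rho_p * math.pi * r**2 * h
    return TestParticle(r=r, h=h, rho_p=rho_p, m=m, label=label)


_PRESETS = {
    "standard_dust": lambda: particle_from_density(
        1000.0, 1e-9, 1e-9, label="standard_dust"
    ),
    "h1n1_virus": lambda: particle_from_mass(
        0.8e-18, 109e-9, 109e-9, label="h1n1_virus"
    ),
    "bacterial_organelle": lambda: particle_from_density(
        2000.0, 2e-6, 40e-9, label="bacterial_organelle"
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> TestParticle:
    """Return one of the built-in particle archetypes by name."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
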