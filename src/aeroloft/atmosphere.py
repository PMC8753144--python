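"""Air density, temperature, mean free path and gravity vs altitude.

The default profile is the US Standard Atmosphere 1976, shipped as a packaged
CSV spanning 0-200 km of geometric altitude. Density and mean free path span
many decades over that range and fall off near-exponentially, so both are
interpolated log-linearly between grid nodes (exact at nodes, geometric mean
at a midpoint); temperature is interpolated linearly. Any table with the same
columns, or any callable backend (e.g. an NRLMSISE-00-style empirical model),
can be substituted for the embedded profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "AltitudeRangeError",
    "AtmosphereProfile",
    "GravityModel",
    "density_at",
    "temperature_at",
    "mean_free_path_at",
    "knudsen_number",
    "gravity_at",
]

#: Standard surface gravity (m s-2).
STANDARD_G0 = 9.80665
#: Mean Earth radius (m) used by the inverse-square gravity model.
MEAN_EARTH_RADIUS = 6.371e6


class AltitudeRangeError(ValueError):
    """Requested altitude lies outside the profile's tabulated span."""


@dataclass(frozen=True)
class AtmosphereProfile:
    """Tabulated atmosphere: per-altitude density, temperature, mean free path.

    Parameters
    ----------
    altitudes
        Geometric altitude grid in metres, strictly increasing.
    densities
        Air mass density at each node (kg m-3), strictly positive.
    temperatures
        Kinetic temperature at each node (K).
    mean_free_paths
        Equilibrium mean free path at each node (m).
    source_label
        Free-text provenance of the table.
    """

    altitudes: np.ndarray
    densities: np.ndarray
    temperatures: np.ndarray
    mean_free_paths: np.ndarray
    source_label: str = "user"

    def __post_init__(self) -> None:
        for name in ("altitudes", "densities", "temperatures", "mean_free_paths"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        n = self.altitudes.size
        if any(
            getattr(self, name).size != n
            for name in ("densities", "temperatures", "mean_free_paths")
        ):
            raise ValueError("all per-altitude columns must have equal length")
        if n < 2:
            raise ValueError("profile needs at least two altitude nodes")
        if not np.all(np.diff(self.altitudes) > 0):
            raise ValueError("altitude grid must be strictly increasing")
        if np.any(self.densities <= 0) or np.any(self.mean_free_paths <= 0):
            raise ValueError("densities and mean free paths must be positive")

    @property
    def span(self) -> tuple[float, float]:
        """(z_min, z_max) of the tabulated altitude range, metres."""
        return float(self.altitudes[0]), float(self.altitudes[-1])

    def _check_span(self, z: float) -> float:
        z = float(z)
        lo, hi = self.span
        if not (lo <= z <= hi):
            raise AltitudeRangeError(
                f"altitude {z:g} m outside tabulated span [{lo:g}, {hi:g}] m"
            )
        return z

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source_label: str) -> "AtmosphereProfile":
        required = ["z_m", "rho_kg_m3", "T_K", "mfp_m"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"atmosphere table missing columns: {missing}")
        return cls(
            altitudes=df["z_m"].to_numpy(float),
            densities=df["rho_kg_m3"].to_numpy(float),
            temperatures=df["T_K"].to_numpy(float),
            mean_free_paths=df["mfp_m"].to_numpy(float),
            source_label=source_label,
        )

    @classmethod
    def from_csv(cls, path: str) -> "AtmosphereProfile":
        """Load a profile from a CSV with columns ``z_m,rho_kg_m3,T_K,mfp_m``."""
        return cls.from_frame(pd.read_csv(path), source_label=str(path))

    @classmethod
    def embedded(cls) -> "AtmosphereProfile":
        """The packaged US Standard Atmosphere 1976 table (0-200 km)."""
        with resources.files("aeroloft.data").joinpath("ussa1976.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df, source_label="US Standard Atmosphere 1976")

    @classmethod
    def from_backend(
        cls,
        backend: Callable[[float], tuple[float, float, float]],
        altitudes: np.ndarray,
        source_label: str = "backend",
    ) -> "AtmosphereProfile":
        """Sample a callable empirical model onto a grid.

        ``backend(z)`` must return ``(rho, T, mean_free_path)`` at geometric
        altitude ``z`` in metres. This is the hook for plugging in an
        NRLMSISE-00-style model without changing any downstream code.
        """
        altitudes = np.asarray(altitudes, dtype=float)
        samples = np.array([backend(float(z)) for z in altitudes])
        return cls(
            altitudes=altitudes,
            densities=samples[:, 0],
            temperatures=samples[:, 1],
            mean_free_paths=samples[:, 2],
            source_label=source_label,
        )


@dataclass(frozen=True)
class GravityModel:
    """Gravitational acceleration vs altitude.

    ``inverse_square`` (default) uses g(z) = g0 (R/(R+z))^2 with the mean
    Earth radius; ``constant`` returns g0 at every altitude.
    """

    g0: float = STANDARD_G0
    earth_radius: float = MEAN_EARTH_RADIUS
    mode: Literal["inverse_square", "constant"] = "inverse_square"

    def __post_init__(self) -> None:
        if self.g0 <= 0 or self.earth_radius <= 0:
            raise ValueError("g0 and earth_radius must be positive")


def density_at(profile: AtmosphereProfile, z: float) -> float:
    """Air density (kg m-3) at geometric altitude ``z`` (m), log-linear."""
    z = profile._check_span(z)
    return float(
        np.exp(np.interp(z, profile.altitudes, np.log(profile.densities)))
    )


def temperature_at(profile: AtmosphereProfile, z: float) -> float:
    """Kinetic temperature (K) at altitude ``z`` (m), linear interpolation."""
    z = profile._check_span(z)
    return float(np.interp(z, profile.altitudes, profile.temperatures))


def mean_free_path_at(profile: AtmosphereProfile, z: float) -> float:
    """Equilibrium mean free path (m) at altitude ``z`` (m), log-linear."""
    z = profile._check_span(z)
    return float(
        np.exp(np.interp(z, profile.altitudes, np.log(profile.mean_free_paths)))
    )


def knudsen_number(profile: AtmosphereProfile, z: float, r: float) -> float:
    """Knudsen number Kn = mean free path / particle radius.

    Kn >> 1 places the particle in the kinetic (non-continuum) regime; the
    directed-flow drag model is applied there as the zeroth-order description
    of a sustained bulk updraft.
    """
    if r <= 0:
        raise ValueError("particle radius must be positive")
    return mean_free_path_at(profile, z) / r


def gravity_at(model: GravityModel, z: float) -> float:
    """Gravitational acceleration (m s-2) at altitude ``z`` (m)."""
    z = float(z)
    if z < 0:
        raise ValueError(f"altitude must be non-negative, got {z:g} m")
    if model.mode == "constant":
        return model.g0
    ratio = model.earth_radius / (model.earth_radius + z)
    return model.g0 * ratio * ratio
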