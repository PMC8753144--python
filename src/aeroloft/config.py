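"""Scenario configuration: validation and boundary-layer unit parsing.

Scenarios are described by a single JSON document (or equivalent CLI flags).
Particles may be given as ``preset:<name>`` or as a spec string like
``r=2um,h=40nm,rho=2000`` (unit suffixes nm/um/mm/m are parsed here; the
library itself is strictly SI).
"""
from __future__ import annotations

import re
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, model_validator

from .atmosphere import AtmosphereProfile, GravityModel
from .particles import TestParticle, particle_from_density, particle_from_mass, preset

__all__ = [
    "ScenarioConfig",
    "ConstantWindSpec",
    "CsvWindSpec",
    "SynthWindSpec",
    "parse_length",
    "parse_particle_spec",
]

_LENGTH_UNITS = {"nm": 1e-9, "um": 1e-6, "µm": 1e-6, "mm": 1e-3, "m": 1.0}
_LENGTH_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(nm|um|µm|mm|m)?\s*$")


def parse_length(text: str) -> float:
    """Parse a length with optional unit suffix (``2um`` -> 2e-6 m)."""
    m = _LENGTH_RE.match(str(text))
    if not m:
        raise ValueError(f"cannot parse length {text!r}")
    value = float(m.group(1))
    return value * _LENGTH_UNITS[m.group(2) or "m"]


def parse_particle_spec(spec: str) -> TestParticle:
    """Parse ``preset:<name>`` or ``r=...,h=...,rho=...`` / ``m=...`` specs."""
    spec = spec.strip()
    if spec.startswith("preset:"):
        return preset(spec.split(":", 1)[1])
    fields: dict[str, str] = {}
    for part in spec.split(","):
        if "=" not in part:
            raise ValueError(f"malformed particle spec component {part!r}")
        key, value = part.split("=", 1)
        fields[key.strip()] = value.strip()
    unknown = set(fields) - {"r", "h", "rho", "m"}
    if unknown:
        raise ValueError(f"unknown particle spec keys: {sorted(unknown)}")
    if "r" not in fields or "h" not in fields:
        raise ValueError("particle spec requires r and h")
    r = parse_length(fields["r"])
    h = parse_length(fields["h"])
    if "rho" in fields and "m" in fields:
        raise ValueError("give either rho or m, not both")
    if "rho" in fields:
        return particle_from_density(float(fields["rho"]), r, h, label=spec)
    if "m" in fields:
        return particle_from_mass(float(fields["m"]), r, h, label=spec)
    raise ValueError("particle spec requires rho or m")


class ConstantWindSpec(BaseModel):
    kind: Literal["constant"] = "constant"
    w: float
    duration: float = Field(gt=0)


class CsvWindSpec(BaseModel):
    kind: Literal["csv"] = "csv"
    path: str


class SynthWindSpec(BaseModel):
    kind: Literal["synth"] = "synth"
    amplitude: float = Field(default=30.0, ge=0)
    period: float = Field(default=1500.0, gt=0)
    noise_sd: float = Field(default=5.0, ge=0)
    mean_offset: float = 10.0
    duration: float = Field(default=3600.0, gt=0)
    dt: float = Field(default=10.0, gt=0)
    seed: Optional[int] = None  # mandatory at validation; see ScenarioConfig


WindSpec = Union[ConstantWindSpec, CsvWindSpec, SynthWindSpec]


class ScenarioConfig(BaseModel):
    """Validated description of a single simulation scenario."""

    name: str = "scenario"
    particle: str
    atmosphere: str = "embedded"  # "embedded" or a CSV path
    gravity: Literal["inverse_square", "constant"] = "inverse_square"
    wind: WindSpec = Field(discriminator="kind")
    z0: float
    dt: float = Field(default=1.0, gt=0)
    mode: Literal["quasi_steady", "full_ode"] = "quasi_steady"
    rho_override: Optional[float] = Field(default=None, gt=0)
    horizontal_wind: Optional[float] = None
    correlation_length: float = Field(default=3e5, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        parse_particle_spec(self.particle)  # raises on malformed spec
        if isinstance(self.wind, SynthWindSpec) and self.wind.seed is None:
            raise ValueError("synthetic wind requires an explicit seed")
        return self

    def build_particle(self) -> TestParticle:
        return parse_particle_spec(self.particle)

    def build_profile(self) -> AtmosphereProfile:
        if self.atmosphere == "embedded":
            return AtmosphereProfile.embedded()
        return AtmosphereProfile.from_csv(self.atmosphere)

    def build_gravity(self) -> GravityModel:
        return GravityModel(mode=self.gravity)
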