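"""Vertical-wind inputs: episodes, time series, CSV I/O and synthesis.

Observed upper-atmosphere vertical winds oscillate between upward and
downward phases with magnitudes of roughly 10-50 m/s and growth periods of
tens of minutes. Real series are supplied as CSV (columns ``t_s,w_m_s``);
for testing and experimentation a seeded generator produces series with the
same qualitative structure: a mean offset plus a sinusoid plus Gaussian
noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "WindEpisode",
    "WindSeries",
    "WindSynthesisParams",
    "WindFormatError",
    "synthesize",
    "read_wind_csv",
    "write_wind_csv",
    "episodes_from_series",
]

_UNIFORM_STEP_RTOL = 1e-6


class WindFormatError(ValueError):
    """A wind CSV violated the expected format."""


@dataclass(frozen=True)
class WindEpisode:
    """A constant vertical wind ``w`` (m/s, up positive) lasting ``duration`` s.

    ``z_ref`` is the reference altitude for density/gravity lookups when the
    episode is used standalone. ``rho_override``, if set, freezes the air
    density seen by the particle for the whole episode — used to reproduce
    estimates made at an assumed constant density.
    """

    w: float
    duration: float
    z_ref: Optional[float] = None
    rho_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("episode duration must be positive")
        if self.rho_override is not None and self.rho_override <= 0:
            raise ValueError("rho_override must be positive")


@dataclass(frozen=True)
class WindSeries:
    """Uniformly sampled vertical-wind time series (up positive)."""

    times: np.ndarray
    winds: np.ndarray
    z_ref: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "winds", np.asarray(self.winds, dtype=float))
        if self.times.size != self.winds.size:
            raise ValueError("times and winds must have equal length")
        if self.times.size < 2:
            raise ValueError("series needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0)) + 1
            raise WindFormatError(
                f"times must be strictly increasing; violation at sample {bad}"
            )
        if np.any(np.abs(steps - steps[0]) > _UNIFORM_STEP_RTOL * steps[0]):
            bad = int(np.argmax(np.abs(steps - steps[0]) > _UNIFORM_STEP_RTOL * steps[0])) + 1
            raise WindFormatError(
                f"time step must be uniform; violation at sample {bad}"
            )

    @property
    def dt(self) -> float:
        """Sample interval (s)."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Total covered duration (s): one sample interval per sample."""
        return self.dt * self.times.size


@dataclass(frozen=True)
class WindSynthesisParams:
    """Parameters of the synthetic wind generator.

    w(t) = mean_offset + amplitude * sin(2 pi t / period) + N(0, noise_sd),
    sampled every ``dt`` seconds for ``duration`` seconds, seeded.

    Defaults emulate the observed oscillatory winds: 30 m/s amplitude around
    a 10 m/s upward mean offset (peaks near 40-50 m/s, troughs downward), a
    25-minute period matching the reported 20-30 min growth to maximum, and
    5 m/s of measurement-scale noise.
    """

    amplitude: float = 30.0
    period: float = 1500.0
    noise_sd: float = 5.0
    mean_offset: float = 10.0
    duration: float = 3600.0
    dt: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        if self.period <= 0 or self.dt <= 0:
            raise ValueError("period and dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must cover at least one sample")


def synthesize(params: WindSynthesisParams) -> WindSeries:
    """Generate a seeded synthetic wind series from ``params``.

    The same parameters and seed always produce the identical series.
    """
    n = int(round(params.duration / params.dt))
    times = np.arange(n) * params.dt
    rng = np.random.default_rng(params.seed)
    winds = (
        params.mean_offset
        + params.amplitude * np.sin(2.0 * math.pi * times / params.period)
        + rng.normal(0.0, params.noise_sd, size=n)
    )
    return WindSeries(
        times=times,
        winds=winds,
        provenance=(
            f"synth(amplitude={params.amplitude},period={params.period},"
            f"noise_sd={params.noise_sd},mean_offset={params.mean_offset},"
            f"duration={params.duration},dt={params.dt},seed={params.seed})"
        ),
    )


def read_wind_csv(path: str) -> WindSeries:
    """Read a wind series from CSV with header ``t_s,w_m_s``."""
    df = pd.read_csv(path)
    missing = [c for c in ("t_s", "w_m_s") if c not in df.columns]
    if missing:
        raise WindFormatError(f"{path}: missing columns {missing}")
    if df[["t_s", "w_m_s"]].isna().any().any():
        bad = int(df[["t_s", "w_m_s"]].isna().any(axis=1).idxmax()) + 2
        raise WindFormatError(f"{path}: unparseable row at line {bad}")
    try:
        return WindSeries(
            times=df["t_s"].to_numpy(float),
            winds=df["w_m_s"].to_numpy(float),
            provenance=str(path),
        )
    except WindFormatError as exc:
        raise WindFormatError(f"{path}: {exc}") from None


def write_wind_csv(series: WindSeries, path: str) -> None:
    """Write a wind series as CSV with header ``t_s,w_m_s``."""
    pd.DataFrame({"t_s": series.times, "w_m_s": series.winds}).to_csv(
        path, index=False, float_format="%.12g"
    )


def episodes_from_series(
    series: WindSeries, threshold: float
) -> list[WindEpisode]:
    """Segment a series into maximal runs at or above / below ``threshold``.

    Samples with w >= threshold form ascent episodes, the gaps between them
    sub-threshold episodes. Each episode carries the run-mean wind (the
    conservative choice for climb estimates) and a duration of one sample
    interval per sample, so episode durations sum exactly to the series
    duration.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    winds = series.winds
    if winds.size == 0:
        raise ValueError("empty wind series")
    dt = series.dt
    above = winds >= threshold
    episodes: list[WindEpisode] = []
    start = 0
    for i in range(1, winds.size + 1):
        if i == winds.size or above[i] != above[start]:
            run = winds[start:i]
            episodes.append(
                WindEpisode(
                    w=float(run.mean()),
                    duration=dt * run.size,
                    z_ref=series.z_ref,
                )
            )
            start = i
    return episodes
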