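"""Eustatic sea-level curves: the external driver of stratigraphic architecture.

Three sources are provided:

* :func:`sinusoidal_sealevel` — a composite of sinusoids. The default emulates a
  third-order cycle (amplitude 20 m, period 1 Myr) superposed with fourth-order
  cycles (amplitude 2 m, period 0.112 Myr) over 2 Myr, the forcing behind a
  platform with two long emersion gaps.
* :func:`synthetic_glacioeustatic_sealevel` — a Pleistocene-like stand-in:
  41-kyr obliquity-paced oscillations whose amplitude ramps up through the
  early Pleistocene, switching to quasi-100-kyr cyclicity with a 140 m
  peak-to-trough range over the youngest 0.8 Myr. This is an explicit
  emulation of the shape of published Pleistocene global mean sea-level
  estimates, not a reconstruction of any specific curve.
* :func:`load_sealevel_table` — reads an empirical two-column (age, elevation)
  table, interpolates it onto the model's uniform time grid and optionally
  normalizes it to zero mean.

Internal units are Myr and metres throughout; loaders convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import as_rng

__all__ = [
    "SeaLevelCurve",
    "sinusoidal_sealevel",
    "synthetic_glacioeustatic_sealevel",
    "load_sealevel_table",
    "DEFAULT_SINUSOID_COMPONENTS",
]

#: (amplitude m, period Myr, phase rad) of the default composite sinusoid
DEFAULT_SINUSOID_COMPONENTS: tuple[tuple[float, float, float], ...] = (
    (20.0, 1.0, 0.0),
    (2.0, 0.112, 0.0),
)


@dataclass(frozen=True)
class SeaLevelCurve:
    """Eustatic elevation (m) on a uniform time grid of step ``dt`` (Myr).

    ``elevations`` holds one value per step edge from t=0 to the duration,
    i.e. ``len(elevations) == duration/dt + 1``.
    """

    dt: float
    elevations: np.ndarray

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        e = np.asarray(self.elevations, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("elevations must be 1-D with at least two entries")
        if not np.all(np.isfinite(e)):
            raise ValueError("elevations must be finite")
        object.__setattr__(self, "elevations", e)

    @property
    def duration(self) -> float:
        return (self.elevations.size - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.elevations.size) * self.dt

    def at(self, t) -> np.ndarray:
        """Elevation at arbitrary times within the curve (linear within a step)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.duration + 1e-12):
            raise ValueError("time outside the curve")
        return np.interp(t, self.times, self.elevations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_myr": self.times, "elevation_m": self.elevations})


def sinusoidal_sealevel(
    components: Sequence[tuple[float, float, float]] = DEFAULT_SINUSOID_COMPONENTS,
    duration: float = 2.0,
    dt: float = 0.001,
) -> SeaLevelCurve:
    """Composite sinusoidal eustasy: ``sum_i a_i sin(2 pi t / p_i + phi_i)``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = round(duration / dt)
    if abs(n * dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    t = np.arange(n + 1) * dt
    elev = np.zeros_like(t)
    for amp, period, phase in components:
        if period <= 0:
            raise ValueError("periods must be positive")
        elev += amp * np.sin(2 * np.pi * t / period + phase)
    return SeaLevelCurve(dt, elev)


def synthetic_glacioeustatic_sealevel(
    duration: float = 2.58,
    dt: float = 0.001,
    transition_before_end: float = 0.8,
    old_period: float = 0.041,
    young_period: float = 0.1,
    old_range: float = 50.0,
    young_range: float = 140.0,
    noise_sd: float = 0.0,
    seed=0,
) -> SeaLevelCurve:
    """Pleistocene-like glacioeustatic stand-in.

    The older segment oscillates with ``old_period`` and a peak-to-trough range
    ramping linearly from half of ``old_range`` up to ``old_range`` (the onset
    of Northern-Hemisphere glaciation); the youngest ``transition_before_end``
    Myr oscillate with ``young_period`` and range ``young_range`` (the
    mid-Pleistocene transition). Optional AR(1) red noise of innovation SD
    ``noise_sd`` is added; the final curve is normalized to mean 0.
    """
    if transition_before_end >= duration:
        raise ValueError("transition_before_end must be < duration")
    if old_range < 0 or young_range < 0:
        raise ValueError("ranges must be non-negative")
    n = round(duration / dt)
    t = np.arange(n + 1) * dt
    t_switch = duration - transition_before_end
    old = t <= t_switch
    elev = np.empty_like(t)
    # amplitude = half of the peak-to-trough range
    ramp = 0.5 * old_range * (0.5 + 0.5 * t[old] / max(t_switch, dt))
    elev[old] = ramp * np.sin(2 * np.pi * t[old] / old_period)
    elev[~old] = 0.5 * young_range * np.sin(
        2 * np.pi * (t[~old] - t_switch) / young_period
    )
    if noise_sd > 0:
        rng = as_rng(seed)
        noise = np.empty_like(t)
        # AR(1) with lag-1 correlation 0.9 at the native step
        phi = 0.9
        innov = rng.standard_normal(t.size) * noise_sd
        noise[0] = innov[0]
        for i in range(1, t.size):
            noise[i] = phi * noise[i - 1] + innov[i]
        elev = elev + noise
    elev = elev - elev.mean()
    return SeaLevelCurve(dt, elev)


def load_sealevel_table(
    path,
    dt: float = 0.001,
    normalize: bool = True,
    age_unit: str = "myr",
    duration: float | None = None,
) -> SeaLevelCurve:
    """Load an (age, elevation) table and resample it onto a uniform grid.

    Ages must be strictly monotone (either direction; descending
    ages-before-present are flipped into forward model time). ``age_unit`` is
    ``"myr"`` or ``"ka"``. Linear interpolation onto the ``dt`` grid happens
    first; if ``normalize``, the mean is subtracted afterwards.
    """
    frame = pd.read_csv(path, comment="#")
    if frame.shape[1] < 2 or len(frame) < 2:
        raise ValueError("need at least two rows of (age, elevation)")
    age = frame.iloc[:, 0].to_numpy(dtype=float)
    elev = frame.iloc[:, 1].to_numpy(dtype=float)
    if age_unit == "ka":
        age = age / 1000.0
    elif age_unit != "myr":
        raise ValueError("age_unit must be 'myr' or 'ka'")
    d = np.diff(age)
    if np.all(d < 0):
        age, elev = age[::-1], elev[::-1]
    elif not np.all(d > 0):
        raise ValueError("ages must be strictly monotone")
    t0 = age[0]
    span = age[-1] - t0
    want = span if duration is None else duration
    if want > span + 1e-12:
        raise ValueError("table covers less time than requested duration")
    n = round(want / dt)
    grid = np.arange(n + 1) * dt
    out = np.interp(grid + t0, age, elev)
    if normalize:
        out = out - out.mean()
    return SeaLevelCurve(dt, out)
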