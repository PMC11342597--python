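"""Age-depth models: the coordinate transformation between time and height.

An age-depth model (ADM) at one location is the monotone correspondence
between elapsed time and accumulated stratigraphic height. It is stored as
cumulative height at every step edge of the native time grid (step ``dt``,
typically 1 kyr). Flat stretches are hiatuses: intervals of time with no
preserved deposition. Two derived statistics characterize the record:

* completeness — the fraction of time steps with sediment accumulation,
  measured at the native step resolution;
* the hiatus-duration distribution — lengths of maximal runs of
  non-depositional steps (consecutive gaps merge into one hiatus).

Within one depositing step, accumulation is assumed uniform, so both
directions of the map interpolate linearly inside a step. A height attained
just before a hiatus maps to its *earliest* attainment time (the deposition
time), never to the re-flooding time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeDepthModel",
    "adm_from_column",
    "piecewise_adm",
    "height_at_time",
    "time_at_height",
    "deposition_times",
    "completeness",
    "hiatus_durations",
    "read_adm_table",
]

_H_TOL = 1e-12  # heights below this per step count as non-depositional


@dataclass(frozen=True)
class AgeDepthModel:
    """Cumulative height (m) at each step edge of a uniform time grid (Myr).

    ``heights`` has length N+1, starts at 0 and is non-decreasing.
    """

    dt: float
    heights: np.ndarray

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 1 or h.size < 2:
            raise ValueError("heights must be 1-D with at least two entries")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        if abs(h[0]) > _H_TOL:
            raise ValueError("heights must start at 0")
        if np.any(np.diff(h) < -_H_TOL):
            raise ValueError("heights must be non-decreasing")
        object.__setattr__(self, "heights", h)

    @property
    def n_steps(self) -> int:
        return self.heights.size - 1

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def final_height(self) -> float:
        return float(self.heights[-1])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.heights.size) * self.dt

    def increments(self) -> np.ndarray:
        return np.diff(self.heights)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_myr": self.times, "height_m": self.heights})


def adm_from_column(thicknesses, dt: float) -> AgeDepthModel:
    """Build an ADM from per-step deposited thicknesses at one location."""
    th = np.asarray(thicknesses, dtype=float)
    if np.any(th < -_H_TOL):
        raise ValueError("per-step thicknesses must be non-negative")
    return AgeDepthModel(dt, np.concatenate(([0.0], np.cumsum(np.maximum(th, 0.0)))))


def piecewise_adm(
    segments: Sequence[tuple[float, float]], dt: float | None = None
) -> AgeDepthModel:
    """Hand-crafted ADM from (duration Myr, accumulation rate m/Myr) segments.

    If ``dt`` is not given it defaults to the greatest common divisor of the
    segment durations (at 1-yr resolution). Zero-rate segments are hiatuses.
    """
    if not segments:
        raise ValueError("need at least one segment")
    for dur, rate in segments:
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        if rate < 0:
            raise ValueError("accumulation rates must be >= 0")
    if dt is None:
        # gcd at 1e-6 Myr (one year) resolution
        ints = [round(dur / 1e-6) for dur, _ in segments]
        g = 0
        for i in ints:
            g = math.gcd(g, i)
        dt = g * 1e-6
    th = []
    for dur, rate in segments:
        n = round(dur / dt)
        if abs(n * dt - dur) > 1e-9:
            raise ValueError("segment durations must be multiples of dt")
        th.extend([rate * dt] * n)
    return adm_from_column(th, dt)


def height_at_time(adm: AgeDepthModel, t) -> np.ndarray | float:
    """Cumulative height at time ``t`` (uniform accumulation within a step)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > adm.duration + 1e-12):
        raise ValueError("t outside [0, duration]")
    out = np.interp(t_arr, adm.times, adm.heights)
    return float(out) if np.isscalar(t) else out


def time_at_height(adm: AgeDepthModel, h: float) -> float:
    """Deposition time of height ``h``: earliest time the ADM attains it."""
    return float(deposition_times(adm, [h])[0])


def deposition_times(adm: AgeDepthModel, heights) -> np.ndarray:
    """Vectorized earliest-attainment times for the given heights (m)."""
    h = np.asarray(heights, dtype=float)
    if np.any(h < -_H_TOL) or np.any(h > adm.final_height + _H_TOL):
        raise ValueError("height outside [0, final height]")
    h = np.clip(h, 0.0, adm.final_height)
    c = adm.heights
    idx = np.searchsorted(c, h, side="left")
    out = np.empty(h.shape, dtype=float)
    at_start = idx == 0
    out[at_start] = 0.0
    inner = ~at_start
    i = idx[inner]
    denom = c[i] - c[i - 1]
    frac = np.where(denom > 0, (h[inner] - c[i - 1]) / np.where(denom > 0, denom, 1.0), 1.0)
    out[inner] = (i - 1 + frac) * adm.dt
    return out


def completeness(adm: AgeDepthModel) -> float:
    """Fraction of time steps with sediment accumulation, at the native dt."""
    return float(np.mean(adm.increments() > _H_TOL))


def hiatus_durations(adm: AgeDepthModel) -> np.ndarray:
    """Durations (Myr) of maximal runs of non-depositional steps."""
    gap = adm.increments() <= _H_TOL
    if not gap.any():
        return np.empty(0)
    # run-length encode the gap mask
    edges = np.diff(np.concatenate(([0], gap.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return (ends - starts) * adm.dt


def read_adm_table(path) -> AgeDepthModel:
    """Read a two-column (time_myr, height_m) table; validates monotonicity."""
    frame = pd.read_csv(path)
    t = frame["time_myr"].to_numpy(dtype=float)
    h = frame["height_m"].to_numpy(dtype=float)
    d = np.diff(t)
    if t.size < 2 or np.any(d <= 0):
        raise ValueError("time column must be strictly increasing")
    if abs(d.min() - d.max()) > 1e-9:
        raise ValueError("time column must be uniformly spaced")
    return AgeDepthModel(float(d[0]), h)
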