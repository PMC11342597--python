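"""Continuous-time simulators of the three modes of phenotypic evolution.

Two process families are supported:

* **Brownian drift** ``X_t = x0 + mu * t + sigma * B_t`` — the continuous-time
  extension of (un)biased random walks. After ``t`` Myr the trait is normally
  distributed with mean ``x0 + mu * t`` and standard deviation ``sigma * sqrt(t)``.
  Brownian motion (the unbiased random walk) is the special case ``mu = 0``.
* **Stasis** — trait values are i.i.d. ``Normal(m, s^2)`` draws, independent of
  the spacing of observation times.

Both are evaluable at arbitrary strictly increasing time points *without
interpolation*: Brownian drift is generated from exact Gaussian increments over
the requested time gaps, so the finite-dimensional distributions are identical
whether a lineage is simulated on a coarse grid directly or on a fine grid and
sub-sampled. This matters because stratigraphic sampling produces heavily
irregular ("heterodistant") observation times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_rng, validate_times

__all__ = [
    "BrownianDriftParams",
    "StasisParams",
    "TraitSeries",
    "sample_brownian_drift",
    "sample_stasis",
    "simulate_lineage",
    "expected_moments",
]


@dataclass(frozen=True)
class BrownianDriftParams:
    """Brownian drift parameters.

    mu
        Drift (trait units per Myr); directionality of evolution.
    sigma
        Volatility (trait units per sqrt(Myr)).
    x0
        Trait value at t = 0 (the process is anchored at the start of the
        observation window even if the first sampled time is later).
    """

    mu: float
    sigma: float
    x0: float = 0.0

    def __post_init__(self):
        for name in ("mu", "sigma", "x0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class StasisParams:
    """Stasis parameters: mean ``m`` and standard deviation ``s`` of the
    i.i.d. trait distribution."""

    m: float
    s: float

    def __post_init__(self):
        if not (np.isfinite(self.m) and np.isfinite(self.s)):
            raise ValueError("stasis parameters must be finite")
        if self.s < 0:
            raise ValueError("s must be >= 0")


@dataclass(frozen=True)
class TraitSeries:
    """True lineage values at strictly increasing time points (Myr)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = validate_times(self.times)
        v = np.asarray(self.values, dtype=float)
        if v.shape != t.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(v)):
            raise ValueError("trait values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def at(self, times) -> np.ndarray:
        """Values at a subset of the stored times (exact match required)."""
        idx = np.searchsorted(self.times, times)
        if np.any(idx >= len(self)) or not np.allclose(self.times[idx], times):
            raise KeyError("requested times were not simulated")
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_myr": self.times, "trait": self.values})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraitSeries":
        return cls(frame["time_myr"].to_numpy(), frame["trait"].to_numpy())


def sample_brownian_drift(times, params: BrownianDriftParams, seed) -> TraitSeries:
    """Simulate one Brownian-drift lineage exactly at the requested times.

    The first value is drawn over the gap [0, t1] from the anchor ``x0``;
    successive increments over (t_i, t_{i+1}) are independent
    ``Normal(mu * dt, sigma^2 * dt)``. A fixed seed gives identical output.
    """
    t = validate_times(times)
    rng = as_rng(seed)
    # gaps from the t=0 anchor through all sampled times
    dt = np.diff(np.concatenate(([0.0], t)))
    incr = params.mu * dt + params.sigma * np.sqrt(dt) * rng.standard_normal(t.size)
    return TraitSeries(t, params.x0 + np.cumsum(incr))


def sample_stasis(times, params: StasisParams, seed) -> TraitSeries:
    """Simulate a stasis lineage: i.i.d. Normal(m, s^2) values at the times.

    The distribution depends only on the number of observations, never on
    their spacing, so stasis is untouched by heterodistant sampling.
    """
    t = validate_times(times)
    rng = as_rng(seed)
    return TraitSeries(t, params.m + params.s * rng.standard_normal(t.size))


def simulate_lineage(params, times, seed) -> TraitSeries:
    """Dispatch on parameter type (BrownianDriftParams or StasisParams)."""
    if isinstance(params, BrownianDriftParams):
        return sample_brownian_drift(times, params, seed)
    if isinstance(params, StasisParams):
        return sample_stasis(times, params, seed)
    raise TypeError(f"unknown model parameters: {type(params).__name__}")


def expected_moments(params, t: float) -> tuple[float, float]:
    """Analytic (mean, sd) of the trait at time ``t`` under the model."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if isinstance(params, BrownianDriftParams):
        return params.x0 + params.mu * t, params.sigma * float(np.sqrt(t))
    if isinstance(params, StasisParams):
        return params.m, params.s
    raise TypeError(f"unknown model parameters: {type(params).__name__}")
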