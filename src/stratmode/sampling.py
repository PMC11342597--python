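"""Population sampling in the time and stratigraphic domains.

A *stratophenetic series* is built by (1) choosing equidistant sampling
heights in a section, (2) mapping each height to its deposition time through
the age-depth model, (3) simulating the trait lineage exactly at those times,
and (4) drawing a population sample (specimen mean and variance) at each
position. The resulting (height, time, mean) triplets carry both coordinates,
so the same lineage can be compared between domains.

The default sampling scheme is one sample per metre, 100 specimens per
sample, within-sample trait variance 0.1 — small relative to the evolutionary
change accumulating over Myr timescales, so population noise rarely masquerades
as a trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_rng, merge_time_grids, spawn_seeds, validate_times
from .age_depth import AgeDepthModel, deposition_times
from .trait_models import TraitSeries, simulate_lineage

__all__ = [
    "PhenoSeries",
    "sampling_heights",
    "equidistant_times",
    "draw_sample",
    "build_series",
]


@dataclass(frozen=True)
class PhenoSeries:
    """Sampled population series: one (mean, variance, n) per position.

    ``positions`` are heights (m) in the stratigraphic domain or times (Myr)
    in the time domain; ``deposition_time`` always holds the true formation
    time of each position.
    """

    positions: np.ndarray
    sample_mean: np.ndarray
    sample_var: np.ndarray
    n: np.ndarray
    domain: str  # "time" | "stratigraphic"
    deposition_time: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        mean = np.asarray(self.sample_mean, dtype=float)
        var = np.asarray(self.sample_var, dtype=float)
        n = np.asarray(self.n, dtype=int)
        dep = np.asarray(self.deposition_time, dtype=float)
        if not (pos.shape == mean.shape == var.shape == n.shape == dep.shape):
            raise ValueError("all fields must have equal length")
        if pos.size == 0:
            raise ValueError("series must contain at least one sample")
        if pos.size > 1 and np.min(np.diff(pos)) <= 0:
            raise ValueError("positions must be strictly increasing")
        if np.any(var < 0) or np.any(n < 1):
            raise ValueError("need sample_var >= 0 and n >= 1")
        if self.domain not in ("time", "stratigraphic"):
            raise ValueError("domain must be 'time' or 'stratigraphic'")
        for name, arr in (
            ("positions", pos),
            ("sample_mean", mean),
            ("sample_var", var),
            ("n", n),
            ("deposition_time", dep),
        ):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.positions.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "deposition_time_myr": self.deposition_time,
                "mean": self.sample_mean,
                "var": self.sample_var,
                "n": self.n,
                "domain": self.domain,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhenoSeries":
        domains = frame["domain"].unique()
        if len(domains) != 1:
            raise ValueError("a series must live in a single domain")
        return cls(
            frame["position"].to_numpy(),
            frame["mean"].to_numpy(),
            frame["var"].to_numpy(),
            frame["n"].to_numpy(),
            str(domains[0]),
            frame["deposition_time_myr"].to_numpy(),
        )


def sampling_heights(adm: AgeDepthModel, spacing: float = 1.0) -> np.ndarray:
    """Equidistant sampling heights k * spacing up to the section top.

    Height 0 (the pre-simulation surface) is excluded; the result may be
    empty for very thin sections.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    k = int(np.floor(adm.final_height / spacing + 1e-9))
    return spacing * np.arange(1, k + 1)


def equidistant_times(duration: float, n_points: int) -> np.ndarray:
    """``n_points`` equally spaced times from 0 to ``duration`` inclusive."""
    if n_points < 2:
        raise ValueError("need at least two sampling points")
    return np.linspace(0.0, duration, n_points)


def draw_sample(
    true_mean: float, within_var: float = 0.1, n: int = 100, seed=None
) -> tuple[float, float]:
    """Draw ``n`` specimens Normal(true_mean, within_var); return their
    empirical mean and unbiased variance."""
    if within_var < 0:
        raise ValueError("within_var must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2 specimens for a variance")
    if within_var == 0:
        return float(true_mean), 0.0
    rng = as_rng(seed)
    spec = true_mean + np.sqrt(within_var) * rng.standard_normal(n)
    return float(spec.mean()), float(spec.var(ddof=1))


def build_series(
    params,
    *,
    heights=None,
    adm: AgeDepthModel | None = None,
    times=None,
    n_specimens: int = 100,
    within_var: float = 0.1,
    seed=None,
    extra_times=None,
) -> tuple[PhenoSeries, TraitSeries]:
    """Simulate one lineage and sample it at the requested positions.

    Exactly one of (``heights`` with ``adm``) or ``times`` must be given.
    The lineage is simulated on the union of the sampling times and any
    ``extra_times`` (e.g. a fine time grid for plotting the true history),
    so the returned :class:`TraitSeries` is the *same* lineage in both
    domains. Returns ``(sampled series, true lineage on the union grid)``.
    """
    if (heights is None) == (times is None):
        raise ValueError("give either heights (with adm) or times")
    if heights is not None:
        if adm is None:
            raise ValueError("stratigraphic sampling requires an age-depth model")
        h = np.asarray(heights, dtype=float)
        if h.size == 0:
            raise ValueError("no sampling positions")
        if np.any(h > adm.final_height + 1e-9):
            raise ValueError("sampling height above the section top")
        sample_times = deposition_times(adm, h)
        positions = h
        domain = "stratigraphic"
    else:
        sample_times = validate_times(times)
        positions = sample_times
        domain = "time"

    union = sample_times
    if extra_times is not None:
        union = merge_time_grids(sample_times, extra_times)
    union = validate_times(union)

    lineage_seed, sampling_seed = spawn_seeds(seed, 2)
    lineage = simulate_lineage(params, union, lineage_seed)
    true_means = lineage.at(sample_times)

    rng = as_rng(sampling_seed)
    means = np.empty(true_means.size)
    varis = np.empty(true_means.size)
    for i, m in enumerate(true_means):
        means[i], varis[i] = draw_sample(m, within_var, n_specimens, rng)
    series = PhenoSeries(
        positions=positions,
        sample_mean=means,
        sample_var=varis,
        n=np.full(true_means.size, n_specimens),
        domain=domain,
        deposition_time=sample_times,
    )
    return series, lineage
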