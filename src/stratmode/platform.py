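"""Simplified forward model of attached carbonate-platform growth.

A 2-D grid (strike x dip, 100 m cells) evolves under eustatic sea-level
forcing, constant subsidence, depth-dependent carbonate production by three
factories, a small cellular-automaton occupancy model, and downslope sediment
transport. Per time step (default 1 kyr) the model records deposited
thickness, the facies (primary per factory, or a "transported" secondary
facies per source factory), and water depth at every cell.

Key behaviors:

* production is zero when a cell is subaerially exposed (water depth <= 0),
  constant at ``g_max`` down to a plateau depth, and decays exponentially
  below it with an e-folding ``decay_scale``;
* in-situ deposition is capped at the current water depth, so the platform
  top tracks sea level and lowstands force hiatuses;
* a fixed fraction of each cell's production cascades down-dip to the nearest
  local topographic low (or the basinward boundary), conserving total volume;
* factory occupancy persists while submerged, dies on exposure, and barren
  flooded cells are recolonized by a uniformly drawn factory after an
  optional lag.

The cellular-automaton rules are deliberately minimal (persistence + uniform
recolonization, optional neighbor-count survival window); downstream
statistics used for inference are chosen not to hinge on CA details.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_rng
from .sealevel import SeaLevelCurve

__all__ = [
    "FactoryParams",
    "DEFAULT_FACTORIES",
    "PlatformConfig",
    "PlatformRecord",
    "Column",
    "production_rate",
    "ca_update",
    "transport_step",
    "simulate_platform",
    "extract_column",
    "wheeler_table",
]

FACIES_NONE = 0  # hiatus / no deposition
# facies codes 1..3 are in-situ factory deposits, 4..6 transported equivalents
FACIES_NAMES = {0: "none", 1: "F1", 2: "F2", 3: "F3", 4: "F1T", 5: "F2T", 6: "F3T"}


@dataclass(frozen=True)
class FactoryParams:
    """Depth-dependent production curve of one carbonate factory.

    Production is ``g_max`` (m/Myr) from the surface down to ``plateau_depth``
    (m) and decays as ``exp(-(depth - plateau) / decay_scale)`` below it.
    """

    id: int
    g_max: float
    plateau_depth: float
    decay_scale: float

    def __post_init__(self):
        if self.id not in (1, 2, 3):
            raise ValueError("factory id must be 1, 2 or 3")
        if self.g_max <= 0 or self.plateau_depth <= 0 or self.decay_scale <= 0:
            raise ValueError("factory parameters must be positive")


#: Factory 1 is the phototrophic shallow-water producer (500 m/Myr to 30 m);
#: factories 2 and 3 produce 160 and 150 m/Myr down to 40 m and differ in how
#: fast production decays below the plateau.
DEFAULT_FACTORIES: tuple[FactoryParams, ...] = (
    FactoryParams(1, 500.0, 30.0, 10.0),
    FactoryParams(2, 160.0, 40.0, 20.0),
    FactoryParams(3, 150.0, 40.0, 40.0),
)


@dataclass(frozen=True)
class PlatformConfig:
    sea_level: SeaLevelCurve
    duration: float = 2.0  # Myr
    dt: float = 0.001  # Myr
    n_strike: int = 10
    n_dip: int = 150
    cell_size: float = 100.0  # m
    subsidence: float = 70.0  # m/Myr, uniform
    depth_gradient: float = 80.0 / 15.0  # m per km of dip; 0 m at the shore
    factories: tuple[FactoryParams, ...] = DEFAULT_FACTORIES
    transport_fraction: float = 0.3
    recolonization_lag: int = 0  # steps a flooded barren cell waits
    neighbor_rule: tuple[int, int] | None = None  # (min, max) occupied neighbors
    initial_depth: np.ndarray | None = None  # override the linear ramp (m)
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_strike <= 0 or self.n_dip <= 0 or self.cell_size <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.duration > self.sea_level.duration + 1e-12:
            raise ValueError("sea-level curve shorter than the simulation")
        if not 0.0 <= self.transport_fraction <= 1.0:
            raise ValueError("transport_fraction must be in [0, 1]")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    def initial_depth_profile(self) -> np.ndarray:
        """(n_strike, n_dip) initial water depth, linear ramp from the shore."""
        if self.initial_depth is not None:
            d = np.broadcast_to(
                np.asarray(self.initial_depth, dtype=float),
                (self.n_strike, self.n_dip),
            )
            return d.copy()
        dip_km = (np.arange(self.n_dip) + 0.5) * self.cell_size / 1000.0
        return np.broadcast_to(
            self.depth_gradient * dip_km, (self.n_strike, self.n_dip)
        ).copy()


@dataclass
class PlatformRecord:
    """Per-step, per-cell simulation output (time, strike, dip)."""

    config: PlatformConfig
    thickness: np.ndarray  # m deposited in each step
    facies: np.ndarray  # int8 codes, see FACIES_NAMES
    water_depth: np.ndarray  # m at the start of each step

    @property
    def dt(self) -> float:
        return self.config.dt

    @property
    def middle_strike(self) -> int:
        return self.config.n_strike // 2

    def cumulative_height(self) -> np.ndarray:
        """(strike, dip) total deposited thickness."""
        return self.thickness.sum(axis=0, dtype=float)


@dataclass(frozen=True)
class Column:
    """Per-step history at a single grid cell."""

    dt: float
    thickness: np.ndarray
    facies: np.ndarray
    dip_km: float
    strike_index: int


def production_rate(factory: FactoryParams, water_depth) -> np.ndarray | float:
    """Production (m/Myr) at the given water depth (m); 0 when exposed."""
    wd = np.asarray(water_depth, dtype=float)
    rate = np.where(
        wd <= 0.0,
        0.0,
        np.where(
            wd <= factory.plateau_depth,
            factory.g_max,
            factory.g_max
            * np.exp(-(wd - factory.plateau_depth) / factory.decay_scale),
        ),
    )
    return float(rate) if np.isscalar(water_depth) else rate


def ca_update(
    occupancy: np.ndarray,
    water_depth: np.ndarray,
    rng,
    *,
    recolonization_lag: int = 0,
    neighbor_rule: tuple[int, int] | None = None,
    wait: np.ndarray | None = None,
    factory_ids: tuple[int, ...] = (1, 2, 3),
) -> tuple[np.ndarray, np.ndarray]:
    """One occupancy step: persist, kill exposed, recolonize flooded barren.

    ``wait`` counts remaining lag steps per cell; pass the array returned by
    the previous call. Returns (new occupancy, new wait).
    """
    if occupancy.shape != water_depth.shape:
        raise ValueError("occupancy and water_depth grids must be congruent")
    rng = as_rng(rng)
    occ = occupancy.copy()
    if wait is None:
        wait = np.zeros(occ.shape, dtype=np.int32)
    wait = wait.copy()
    submerged = water_depth > 0.0
    newly_exposed = (~submerged) & (occ > 0)
    occ[~submerged] = 0
    wait[newly_exposed] = recolonization_lag
    if neighbor_rule is not None:
        lo, hi = neighbor_rule
        occupied = (occ > 0).astype(np.int32)
        count = np.zeros_like(occupied)
        count[1:, :] += occupied[:-1, :]
        count[:-1, :] += occupied[1:, :]
        count[:, 1:] += occupied[:, :-1]
        count[:, :-1] += occupied[:, 1:]
        occ[(occ > 0) & ((count < lo) | (count > hi))] = 0
    barren_wet = submerged & (occ == 0)
    ready = barren_wet & (wait <= 0)
    ids = np.asarray(factory_ids, dtype=occ.dtype)
    occ[ready] = ids[rng.integers(0, ids.size, size=int(ready.sum()))]
    waiting = barren_wet & ~ready
    wait[waiting] -= 1
    return occ, wait


def _resting_indices(water_depth: np.ndarray) -> np.ndarray:
    """Down-dip resting cell for a parcel released at each cell.

    A parcel cascades basinward while the next down-dip cell is deeper, and
    settles at the first cell without a deeper neighbor (a local low or the
    basinward boundary).
    """
    s, d = water_depth.shape
    rest = np.empty((s, d), dtype=np.intp)
    rest[:, -1] = d - 1
    for j in range(d - 2, -1, -1):
        deeper = water_depth[:, j + 1] > water_depth[:, j] + 1e-12
        rest[:, j] = np.where(deeper, rest[:, j + 1], j)
    return rest


def transport_step(
    water_depth: np.ndarray,
    produced: np.ndarray,
    transport_fraction: float,
    source: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Redistribute a fraction of production downslope; volume conserving.

    Returns ``(kept, transported)`` where ``kept`` is the in-situ remainder
    and ``transported[f-1]`` the thickness arriving from source factory ``f``
    (all factories pooled in layer 0 when ``source`` is None).
    """
    if not 0.0 <= transport_fraction <= 1.0:
        raise ValueError("transport_fraction must be in [0, 1]")
    if produced.shape != water_depth.shape:
        raise ValueError("grids must be congruent")
    kept = (1.0 - transport_fraction) * produced
    moved = transport_fraction * produced
    transported = np.zeros((3,) + produced.shape)
    if transport_fraction == 0.0 or not np.any(moved > 0):
        return produced.copy(), transported
    rest = _resting_indices(water_depth)
    rows = np.broadcast_to(
        np.arange(produced.shape[0])[:, None], produced.shape
    )
    if source is None:
        np.add.at(transported[0], (rows, rest), moved)
    else:
        for f in (1, 2, 3):
            sel = source == f
            if sel.any():
                np.add.at(
                    transported[f - 1],
                    (rows[sel], rest[sel]),
                    moved[sel],
                )
    return kept, transported


def simulate_platform(config: PlatformConfig) -> PlatformRecord:
    """Run the forward model and record thickness, facies and water depth."""
    n_t, n_s, n_d = config.n_steps, config.n_strike, config.n_dip
    if n_t <= 0:
        raise ValueError("duration must cover at least one step")
    rng = as_rng(config.seed)
    sl = config.sea_level
    sl0 = float(sl.at(0.0))
    depth0 = config.initial_depth_profile()
    g_max = np.array([f.g_max for f in config.factories])
    cum = np.zeros((n_s, n_d))
    # initial occupancy: each cell gets one of the factories or none, uniformly
    ids = np.array([0] + [f.id for f in config.factories], dtype=np.int8)
    occ = ids[rng.integers(0, ids.size, size=(n_s, n_d))]
    wait = np.zeros((n_s, n_d), dtype=np.int32)

    thickness = np.zeros((n_t, n_s, n_d), dtype=np.float32)
    facies = np.zeros((n_t, n_s, n_d), dtype=np.int8)
    wdepth = np.zeros((n_t, n_s, n_d), dtype=np.float32)

    for k in range(n_t):
        t = k * config.dt
        wd = depth0 + config.subsidence * t + (float(sl.at(t)) - sl0) - cum
        wdepth[k] = wd
        occ, wait = ca_update(
            occ,
            wd,
            rng,
            recolonization_lag=config.recolonization_lag,
            neighbor_rule=config.neighbor_rule,
            wait=wait,
            factory_ids=tuple(f.id for f in config.factories),
        )
        rate = np.zeros((n_s, n_d))
        for f in config.factories:
            sel = occ == f.id
            if sel.any():
                rate[sel] = production_rate(f, wd[sel])
        # deposition cannot exceed the accommodation left this step
        produced = np.minimum(rate * config.dt, np.maximum(wd, 0.0))
        kept, transported = transport_step(
            wd, produced, config.transport_fraction, source=occ
        )
        trans_total = transported.sum(axis=0)
        total = kept + trans_total
        thickness[k] = total
        deposited = total > 1e-12
        in_situ_major = kept >= trans_total
        fac = np.zeros((n_s, n_d), dtype=np.int8)
        fac[deposited & in_situ_major] = occ[deposited & in_situ_major]
        sec = deposited & ~in_situ_major
        fac[sec] = (np.argmax(transported, axis=0)[sec] + 4).astype(np.int8)
        # a depositing cell with a barren label can only be transported input
        fac[deposited & (fac == 0)] = 4
        facies[k] = fac
        cum += total
    return PlatformRecord(config, thickness, facies, wdepth)


def extract_column(
    record: PlatformRecord, dip_km: float, strike_index: int | None = None
) -> Column:
    """Per-step history at the cell containing ``dip_km`` (default mid-strike)."""
    cfg = record.config
    extent_km = cfg.n_dip * cfg.cell_size / 1000.0
    if not 0.0 <= dip_km < extent_km:
        raise ValueError(f"dip_km must be in [0, {extent_km}) km")
    idx = int(dip_km * 1000.0 / cfg.cell_size)
    if strike_index is None:
        strike_index = record.middle_strike
    if not 0 <= strike_index < cfg.n_strike:
        raise ValueError("strike_index out of range")
    return Column(
        dt=cfg.dt,
        thickness=record.thickness[:, strike_index, idx].astype(float),
        facies=record.facies[:, strike_index, idx].copy(),
        dip_km=dip_km,
        strike_index=strike_index,
    )


def wheeler_table(record: PlatformRecord, strike_index: int | None = None) -> pd.DataFrame:
    """Tidy (time step, dip, facies) table for chronostratigraphic plots."""
    if strike_index is None:
        strike_index = record.middle_strike
    n_t, _, n_d = record.facies.shape
    steps = np.repeat(np.arange(n_t), n_d)
    dips = np.tile(np.arange(n_d), n_t)
    codes = record.facies[:, strike_index, :].ravel()
    return pd.DataFrame(
        {
            "time_step": steps,
            "dip_cell": dips,
            "facies": pd.Categorical(
                [FACIES_NAMES[c] for c in codes], categories=list(FACIES_NAMES.values())
            ),
        }
    )
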