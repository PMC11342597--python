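"""Scripted experiment drivers: replicate lineages -> series -> model weights.

The drivers regenerate the study's figure data at configurable scale:

* :func:`run_time_domain_grid` — the biasless baseline: lineages under each
  mode of evolution sampled at equidistant time points of increasing density,
  fitted with the three candidate models.
* :func:`run_strat_experiment` — stratophenetic series sampled every metre at
  chosen distances from the shore of a simulated platform, plus a matched
  time-domain baseline of equal series length.
* :func:`platform_profiles` — completeness and hiatus statistics along the
  onshore–offshore gradient.
* :func:`export_triplets` — the (height, time, trait) triplets of one lineage
  for paired stratigraphic/time-domain plots.
* :func:`misselection_rate` — how often a wrong model out-scores the correct
  one across replicates.

Every driver is fully determined by its arguments plus one root seed; output
tables carry the replicate seeds for provenance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._util import merge_time_grids, spawn_seeds
from .age_depth import (
    AgeDepthModel,
    adm_from_column,
    completeness,
    deposition_times,
    hiatus_durations,
)
from .modes import MODELS, compare_models
from .platform import PlatformRecord, extract_column
from .sampling import build_series, equidistant_times, sampling_heights
from .trait_models import BrownianDriftParams, StasisParams, simulate_lineage

__all__ = [
    "MODE_PARAMS",
    "CORRECT_MODEL",
    "run_time_domain_grid",
    "run_strat_experiment",
    "platform_profiles",
    "export_triplets",
    "misselection_rate",
]

#: The three simulated evolutionary scenarios.
MODE_PARAMS = {
    "stasis": StasisParams(m=0.0, s=1.0),
    "bm": BrownianDriftParams(mu=0.0, sigma=1.0),
    "drift": BrownianDriftParams(mu=5.0, sigma=1.0),
}

#: Which fitted model corresponds to each simulated mode.
CORRECT_MODEL = {"stasis": "Stasis", "bm": "URW", "drift": "GRW"}

DEFAULT_N_POINTS = (5, 10, 15, 20, 25, 35, 50, 100, 200)


def _weight_rows(comp, base: dict) -> list[dict]:
    return [
        {**base, "fitted_model": m, "weight": comp.weights[m]} for m in MODELS
    ]


def run_time_domain_grid(
    duration: float = 2.0,
    n_points_list=DEFAULT_N_POINTS,
    modes=("stasis", "bm", "drift"),
    reps: int = 100,
    n_specimens: int = 100,
    within_var: float = 0.1,
    method: str = "joint",
    pool: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Time-domain baseline grid: modes x series lengths x replicates."""
    rows = []
    children = iter(
        spawn_seeds(seed, len(list(modes)) * len(list(n_points_list)) * reps)
    )
    for mode in modes:
        params = MODE_PARAMS[mode]
        for n_points in n_points_list:
            times = equidistant_times(duration, n_points)
            for rep in range(reps):
                child = next(children)
                series, _ = build_series(
                    params,
                    times=times,
                    n_specimens=n_specimens,
                    within_var=within_var,
                    seed=child,
                )
                comp = compare_models(series, method=method, pool=pool)
                rows.extend(
                    _weight_rows(
                        comp,
                        {
                            "scenario": "time",
                            "n_points": n_points,
                            "simulated_mode": mode,
                            "replicate": rep,
                            "series_length": len(series),
                            "seed": int(child.spawn_key[-1]),
                        },
                    )
                )
    return pd.DataFrame(rows)


def run_strat_experiment(
    record: PlatformRecord,
    locations_km=(2.0, 6.0, 8.0, 10.0, 12.0),
    modes=("stasis", "bm", "drift"),
    reps: int = 100,
    spacing: float = 1.0,
    n_specimens: int = 100,
    within_var: float = 0.1,
    method: str = "joint",
    pool: bool = True,
    seed: int = 0,
    with_baseline: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratigraphic-domain experiment plus a matched time-domain baseline.

    Per location, the age-depth model of the mid-strike column is extracted,
    sampling heights are laid out every ``spacing`` metres, and ``reps``
    lineages per mode are pushed through the stratigraphic filter and fitted.
    The baseline simulates time series of the same length over the same
    duration, without stratigraphic distortion. Locations yielding fewer than
    4 samples are skipped with a warning.
    """
    duration = record.config.duration
    rows: list[dict] = []
    base_rows: list[dict] = []
    children = iter(
        spawn_seeds(seed, 2 * len(list(locations_km)) * len(list(modes)) * reps)
    )
    for loc in locations_km:
        column = extract_column(record, loc)
        adm = adm_from_column(column.thickness, column.dt)
        heights = sampling_heights(adm, spacing)
        if heights.size < 4:
            warnings.warn(f"location {loc} km yields {heights.size} samples; skipped")
            continue
        for mode in modes:
            params = MODE_PARAMS[mode]
            for rep in range(reps):
                strat_child = next(children)
                base_child = next(children)
                series, _ = build_series(
                    params,
                    heights=heights,
                    adm=adm,
                    n_specimens=n_specimens,
                    within_var=within_var,
                    seed=strat_child,
                )
                comp = compare_models(series, method=method, pool=pool)
                meta = {
                    "scenario": "stratigraphic",
                    "location_km": loc,
                    "simulated_mode": mode,
                    "replicate": rep,
                    "series_length": len(series),
                    "seed": int(strat_child.spawn_key[-1]),
                }
                rows.extend(_weight_rows(comp, meta))
                if with_baseline:
                    times = equidistant_times(duration, heights.size)
                    bseries, _ = build_series(
                        params,
                        times=times,
                        n_specimens=n_specimens,
                        within_var=within_var,
                        seed=base_child,
                    )
                    bcomp = compare_models(bseries, method=method, pool=pool)
                    base_rows.extend(
                        _weight_rows(
                            bcomp,
                            {**meta, "scenario": "time_baseline",
                             "seed": int(base_child.spawn_key[-1])},
                        )
                    )
    return pd.DataFrame(rows), pd.DataFrame(base_rows)


def platform_profiles(record: PlatformRecord, strike_index: int | None = None) -> pd.DataFrame:
    """Completeness and hiatus-duration summary along the dip transect."""
    if strike_index is None:
        strike_index = record.middle_strike
    cfg = record.config
    rows = []
    for d in range(cfg.n_dip):
        th = record.thickness[:, strike_index, d].astype(float)
        adm = adm_from_column(th, cfg.dt)
        gaps = hiatus_durations(adm)
        if gaps.size:
            q1, med, q3 = np.percentile(gaps, [25, 50, 75])
            gmax = gaps.max()
        else:
            q1 = med = q3 = gmax = np.nan
        rows.append(
            {
                "dip_km": (d + 0.5) * cfg.cell_size / 1000.0,
                "completeness": completeness(adm),
                "n_hiatuses": gaps.size,
                "hiatus_q1": q1,
                "hiatus_median": med,
                "hiatus_q3": q3,
                "hiatus_max": gmax,
                "total_thickness": float(th.sum()),
            }
        )
    return pd.DataFrame(rows)


def export_triplets(
    params,
    adm: AgeDepthModel,
    heights,
    seed: int = 0,
    time_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(height, time, trait) triplets of one lineage, plus its full time path.

    The lineage is simulated once on the union of the deposition times and
    ``time_grid`` (default: 201 equidistant points over the record), so the
    triplet table and the time-domain path describe the same realization.
    """
    h = np.asarray(heights, dtype=float)
    times = deposition_times(adm, h)
    if time_grid is None:
        time_grid = np.linspace(0.0, adm.duration, 201)
    union = merge_time_grids(times, time_grid)
    lineage = simulate_lineage(params, union, seed)
    triplets = pd.DataFrame(
        {"height_m": h, "time_myr": times, "trait": lineage.at(times)}
    )
    path = lineage.to_frame()
    return triplets, path


def misselection_rate(
    table: pd.DataFrame, simulated_mode: str, wrong_model: str
) -> float:
    """Fraction of replicates where ``wrong_model`` out-weighs the correct one."""
    correct = CORRECT_MODEL[simulated_mode]
    sub = table[table["simulated_mode"] == simulated_mode]
    if sub.empty:
        raise ValueError(f"no rows for simulated mode {simulated_mode!r}")
    keys = [c for c in ("scenario", "location_km", "n_points", "replicate") if c in sub]
    wide = sub.pivot_table(
        index=keys, columns="fitted_model", values="weight", aggfunc="first"
    )
    return float(np.mean(wide[wrong_model] > wide[correct]))
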