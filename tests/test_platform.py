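"""Carbonate-platform forward model: production curves, CA occupancy,
transport, accommodation bookkeeping and column extraction."""

import numpy as np
import pytest

from stratmode import (
    DEFAULT_FACTORIES,
    FactoryParams,
    PlatformConfig,
    adm_from_column,
    completeness,
    extract_column,
    hiatus_durations,
    production_rate,
    simulate_platform,
    sinusoidal_sealevel,
)
from stratmode.platform import ca_update, transport_step, wheeler_table
from stratmode.sealevel import SeaLevelCurve


def flat_sealevel(duration=2.0, dt=0.001):
    n = round(duration / dt)
    return SeaLevelCurve(dt, np.zeros(n + 1))


class TestProductionRate:
    def test_plateau_value(self):
        f1 = DEFAULT_FACTORIES[0]
        assert production_rate(f1, 10.0) == pytest.approx(500.0)
        assert production_rate(f1, 30.0) == pytest.approx(500.0)

    def test_exposure_zero(self):
        for f in DEFAULT_FACTORIES:
            assert production_rate(f, -1.0) == 0.0
            assert production_rate(f, 0.0) == 0.0

    def test_e_folding_depth(self):
        for f in DEFAULT_FACTORIES:
            got = production_rate(f, f.plateau_depth + f.decay_scale)
            assert got == pytest.approx(f.g_max / np.e)

    def test_invalid_factory_params(self):
        with pytest.raises(ValueError):
            FactoryParams(1, -5.0, 30.0, 10.0)
        with pytest.raises(ValueError):
            FactoryParams(7, 500.0, 30.0, 10.0)


class TestCAUpdate:
    def test_all_submerged_unchanged(self, rng):
        occ = rng.integers(1, 4, size=(5, 8)).astype(np.int8)
        wd = np.full((5, 8), 10.0)
        new, _ = ca_update(occ, wd, rng, recolonization_lag=0)
        np.testing.assert_array_equal(new, occ)

    def test_exposed_cell_becomes_barren(self, rng):
        occ = np.full((2, 2), 2, dtype=np.int8)
        wd = np.array([[5.0, -1.0], [5.0, 5.0]])
        new, _ = ca_update(occ, wd, rng)
        assert new[0, 1] == 0
        assert (new[wd > 0] == 2).all()

    def test_recolonization_uniform_across_factories(self):
        rng = np.random.default_rng(99)
        occ = np.zeros((100, 100), dtype=np.int8)
        wd = np.full((100, 100), 5.0)
        new, _ = ca_update(occ, wd, rng, recolonization_lag=0)
        counts = np.bincount(new.ravel(), minlength=4)[1:]
        total = counts.sum()
        assert total == 10_000
        # multinomial oracle: each factory frequency within 4 SD of 1/3
        se = np.sqrt((1 / 3) * (2 / 3) / total)
        np.testing.assert_allclose(counts / total, 1 / 3, atol=4 * se)

    def test_recolonization_lag_delays(self, rng):
        occ = np.full((1, 1), 1, dtype=np.int8)
        wd_dry = np.full((1, 1), -1.0)
        wd_wet = np.full((1, 1), 1.0)
        occ, wait = ca_update(occ, wd_dry, rng, recolonization_lag=2)
        assert occ[0, 0] == 0
        occ, wait = ca_update(occ, wd_wet, rng, recolonization_lag=2, wait=wait)
        assert occ[0, 0] == 0  # still waiting
        occ, wait = ca_update(occ, wd_wet, rng, recolonization_lag=2, wait=wait)
        assert occ[0, 0] == 0
        occ, wait = ca_update(occ, wd_wet, rng, recolonization_lag=2, wait=wait)
        assert occ[0, 0] in (1, 2, 3)


class TestTransport:
    def test_fraction_zero_identity(self, rng):
        wd = rng.uniform(0, 50, (4, 10))
        prod = rng.uniform(0, 1, (4, 10))
        kept, trans = transport_step(wd, prod, 0.0)
        np.testing.assert_array_equal(kept, prod)
        assert trans.sum() == 0.0

    def test_flat_topography_no_descent(self, rng):
        wd = np.full((3, 6), 20.0)
        prod = rng.uniform(0, 1, (3, 6))
        kept, trans = transport_step(wd, prod, 0.4)
        # parcels settle where they were released: same per-cell totals
        np.testing.assert_allclose(kept + trans.sum(axis=0), prod)

    def test_volume_conserved_on_random_topography(self, rng):
        wd = rng.uniform(0, 80, (5, 30))
        prod = rng.uniform(0, 2, (5, 30))
        source = rng.integers(1, 4, (5, 30))
        kept, trans = transport_step(wd, prod, 0.3, source=source)
        total = kept.sum() + trans.sum()
        assert abs(total - prod.sum()) / prod.sum() < 1e-9

    def test_monotone_slope_exports_to_deepest(self):
        wd = np.linspace(1, 30, 10)[None, :]
        prod = np.zeros((1, 10))
        prod[0, 0] = 1.0
        kept, trans = transport_step(wd, prod, 1.0)
        assert kept.sum() == 0.0
        assert trans[:, 0, -1].sum() == pytest.approx(1.0)


class TestSimulatePlatform:
    def test_accommodation_cap_fills_to_sea_level(self):
        # no subsidence, flat sea level, 50 m start: column fills to exactly
        # 50 m then stops because water depth is pinned at zero
        cfg = PlatformConfig(
            sea_level=flat_sealevel(duration=0.3),
            duration=0.3,
            n_strike=1,
            n_dip=4,
            subsidence=0.0,
            initial_depth=np.full((1, 4), 50.0),
            factories=(FactoryParams(1, 500.0, 100.0, 10.0),),
            transport_fraction=0.0,
            seed=1,
        )
        record = simulate_platform(cfg)
        totals = record.cumulative_height()
        np.testing.assert_allclose(totals, 50.0, atol=1e-9)

    def test_accumulation_tracks_subsidence_when_filled(self):
        # once depth reaches 0, long-run accumulation rate -> subsidence rate
        cfg = PlatformConfig(
            sea_level=flat_sealevel(duration=1.0),
            duration=1.0,
            n_strike=1,
            n_dip=4,
            subsidence=70.0,
            initial_depth=np.full((1, 4), 5.0),
            factories=(FactoryParams(1, 500.0, 100.0, 10.0),),
            transport_fraction=0.0,
            seed=1,
        )
        record = simulate_platform(cfg)
        th = record.thickness[:, 0, 0].astype(float)
        late = th[500:]  # after the initial fill-up
        rate = late.sum() / (late.size * cfg.dt)
        assert rate == pytest.approx(70.0, rel=1e-6)

    def test_facies_marks_exactly_the_depositional_steps(self, scenario_a_record):
        rec = scenario_a_record
        assert np.all(rec.thickness >= 0)
        # facies "none" <-> zero deposited thickness at that cell/step
        zero = rec.thickness <= 1e-12
        assert np.array_equal(rec.facies == 0, zero)

    def test_lowstand_exposure_forces_hiatuses(self, scenario_a_record):
        # the two long-term sea-level falls leave gaps in platform-top columns
        col = extract_column(scenario_a_record, 2.0)
        adm = adm_from_column(col.thickness, col.dt)
        assert len(hiatus_durations(adm)) >= 2  # two long-term lowstands

    def test_platform_top_column_long_enough(self, scenario_a_record):
        col = extract_column(scenario_a_record, 2.0)
        assert col.thickness.sum() > 25.0

    def test_deterministic_given_seed(self):
        cfg = PlatformConfig(
            sea_level=sinusoidal_sealevel(duration=0.2),
            duration=0.2,
            n_strike=2,
            n_dip=20,
            seed=7,
        )
        a = simulate_platform(cfg)
        b = simulate_platform(cfg)
        np.testing.assert_array_equal(a.thickness, b.thickness)
        np.testing.assert_array_equal(a.facies, b.facies)


class TestExtractColumn:
    @pytest.mark.parametrize(
        "dip_km,index", [(2.0, 20), (6.0, 60), (8.0, 80), (10.0, 100), (12.0, 120)]
    )
    def test_study_locations_map_to_cells(self, scenario_a_record, dip_km, index):
        col = extract_column(scenario_a_record, dip_km)
        np.testing.assert_array_equal(
            col.thickness,
            scenario_a_record.thickness[
                :, scenario_a_record.middle_strike, index
            ].astype(float),
        )

    def test_column_sums_to_final_height(self, scenario_a_record):
        col = extract_column(scenario_a_record, 6.0)
        total = scenario_a_record.cumulative_height()[
            scenario_a_record.middle_strike, 60
        ]
        assert col.thickness.sum() == pytest.approx(total, rel=1e-6)

    def test_out_of_grid_rejected(self, scenario_a_record):
        with pytest.raises(ValueError):
            extract_column(scenario_a_record, 20.0)


def test_wheeler_table_shape(scenario_a_record):
    tab = wheeler_table(scenario_a_record)
    cfg = scenario_a_record.config
    assert len(tab) == cfg.n_steps * cfg.n_dip
    assert set(tab.columns) == {"time_step", "dip_cell", "facies"}
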