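"""Model selection core: likelihoods, AICc, Akaike weights and ML fitting
checked against brute-force oracles and hand-computed values."""

import numpy as np
import pytest
from scipy import stats

from stratmode import (
    BrownianDriftParams,
    PhenoSeries,
    aicc,
    akaike_weights,
    build_series,
    compare_models,
    equidistant_times,
    evidence_ratio,
    fit_model,
    loglik,
    prepare_epsilon,
)
from stratmode._util import spawn_seeds


def make_series(means, varis=None, n=100, times=None):
    means = np.asarray(means, dtype=float)
    if varis is None:
        varis = np.full_like(means, 0.1)
    if times is None:
        times = np.arange(1.0, means.size + 1)
    return PhenoSeries(
        positions=np.asarray(times, dtype=float),
        sample_mean=means,
        sample_var=np.asarray(varis, dtype=float),
        n=np.full(means.size, n),
        domain="time",
        deposition_time=np.asarray(times, dtype=float),
    )


class TestPrepareEpsilon:
    def test_var_over_n(self):
        s = make_series([0, 1, 2], varis=[0.1, 0.1, 0.1], n=100)
        np.testing.assert_allclose(prepare_epsilon(s, pool=False), 0.001)

    def test_pooling_is_noop_for_equal_variances(self):
        s = make_series([0, 1, 2], varis=[0.2, 0.2, 0.2], n=50)
        np.testing.assert_allclose(
            prepare_epsilon(s, pool=True), prepare_epsilon(s, pool=False)
        )

    def test_pooled_equals_weighted_mean(self, rng):
        varis = rng.uniform(0.05, 0.5, 8)
        ns = rng.integers(10, 200, 8)
        s = PhenoSeries(
            positions=np.arange(1.0, 9.0),
            sample_mean=np.zeros(8),
            sample_var=varis,
            n=ns,
            domain="time",
            deposition_time=np.arange(1.0, 9.0),
        )
        pooled = np.sum((ns - 1) * varis) / np.sum(ns - 1)
        np.testing.assert_allclose(prepare_epsilon(s, pool=True), pooled / ns)

    def test_small_samples_rejected(self):
        s = PhenoSeries(
            positions=np.array([1.0, 2.0]),
            sample_mean=np.zeros(2),
            sample_var=np.full(2, 0.1),
            n=np.array([100, 1]),
            domain="time",
            deposition_time=np.array([1.0, 2.0]),
        )
        with pytest.raises(ValueError):
            prepare_epsilon(s)


class TestLoglik:
    def test_single_gaussian_stasis_term(self):
        got = loglik(
            "Stasis",
            {"theta": 0.0, "omega": 0.0},
            [1.0],
            [0.0],
            [0.001],
        )
        assert got == pytest.approx(stats.norm.logpdf(0.0, 0.0, np.sqrt(0.001)))

    def test_ad_urw_matches_per_difference_oracle(self):
        times = np.array([0.0, 0.3, 0.5, 1.1, 2.0])
        means = np.array([0.1, -0.4, 0.2, 0.9, 0.3])
        eps = np.array([0.001, 0.002, 0.001, 0.003, 0.002])
        vstep = 0.7
        got = loglik("URW", {"vstep": vstep}, times, means, eps, method="ad")
        oracle = sum(
            stats.norm.logpdf(
                means[i + 1] - means[i],
                0.0,
                np.sqrt(vstep * (times[i + 1] - times[i]) + eps[i] + eps[i + 1]),
            )
            for i in range(4)
        )
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_joint_matches_multivariate_normal_oracle(self):
        times = np.array([0.0, 0.5, 1.0, 2.0])
        means = np.array([0.0, 0.3, -0.2, 0.8])
        eps = np.full(4, 0.001)
        anc, mstep, vstep = 0.1, 0.4, 0.6
        got = loglik(
            "GRW",
            {"anc": anc, "mstep": mstep, "vstep": vstep},
            times,
            means,
            eps,
        )
        cov = vstep * np.minimum.outer(times, times) + np.diag(eps)
        oracle = stats.multivariate_normal.logpdf(means, anc + mstep * times, cov)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_grw_guarded(self):
        # vstep=0, eps=0: singular covariance -> -inf rather than an error
        got = loglik(
            "GRW",
            {"anc": 0.0, "mstep": 1.0, "vstep": 0.0},
            [0.0, 1.0, 2.0],
            [0.0, 1.0, 2.5],
            [0.0, 0.0, 0.0],
        )
        assert got == -np.inf

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            loglik("URW", {"anc": 0, "vstep": 1}, [0.0, 0.0], [0, 1], [0.001, 0.001])


class TestAicc:
    def test_hand_computed_value(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(25.714285714285715)

    def test_small_sample_penalty(self):
        # K=3, n=5: correction term 2*3*4/(5-3-1) = 24
        assert aicc(-1.0, 3, 5) == pytest.approx(2.0 + 6.0 + 24.0)

    def test_undefined_when_n_too_small(self):
        assert aicc(-1.0, 3, 4) == np.inf


class TestAkaikeWeights:
    def test_equal_values_uniform(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0, 10.0]), 1 / 3)

    def test_two_unit_gap(self):
        w = akaike_weights([0.0, 2.0])
        np.testing.assert_allclose(w, [0.7310585786, 0.2689414214], atol=1e-9)

    def test_infinite_value_gets_zero_weight(self):
        np.testing.assert_allclose(akaike_weights([0.0, np.inf]), [1.0, 0.0])

    def test_all_infinite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([np.inf, np.inf])


class TestFitModel:
    def test_stasis_fit_matches_grid_search_oracle(self, rng):
        means = rng.normal(0.5, 1.0, 10)
        series = make_series(means)
        fit = fit_model(series, "Stasis", method="joint")
        eps = prepare_epsilon(series)
        thetas = np.linspace(means.min(), means.max(), 120)
        omegas = np.geomspace(1e-4, 10.0, 400)
        best = max(
            loglik("Stasis", {"theta": th, "omega": om}, series.positions, means, eps)
            for th in thetas
            for om in omegas
        )
        assert fit.logL >= best - 1e-4

    def test_urw_fit_matches_grid_search_oracle(self, rng):
        times = np.linspace(0.0, 2.0, 12)
        means = np.cumsum(rng.normal(0, 0.4, 12))
        series = make_series(means, times=times)
        fit = fit_model(series, "URW", method="joint")
        eps = prepare_epsilon(series)
        best = max(
            loglik("URW", {"anc": a, "vstep": v}, times, means, eps)
            for a in np.linspace(means.min(), means.max(), 80)
            for v in np.geomspace(1e-4, 10.0, 200)
        )
        assert fit.logL >= best - 1e-4

    def test_degenerate_stasis_recovers_mean_and_floor(self):
        series = make_series([3.0] * 8, varis=[0.0] * 8)
        fit = fit_model(series, "Stasis")
        assert fit.params["theta"] == pytest.approx(3.0, abs=1e-6)
        assert fit.params["omega"] < 1e-6  # pinned at the lower bound

    def test_drift_parameter_recovery(self):
        # mstep within 2 MC SE of mu=5 across replicate fits at n=200
        times = equidistant_times(2.0, 200)
        ests = []
        for s in spawn_seeds(31, 20):
            series, _ = build_series(
                BrownianDriftParams(5.0, 1.0), times=times, seed=s
            )
            ests.append(fit_model(series, "GRW").params["mstep"])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - 5.0) < 2 * se + 1e-9

    def test_vstep_recovery(self):
        times = equidistant_times(2.0, 200)
        ests = []
        for s in spawn_seeds(32, 20):
            series, _ = build_series(
                BrownianDriftParams(0.0, 1.0), times=times, seed=s
            )
            ests.append(fit_model(series, "URW").params["vstep"])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - 1.0) < 2 * se + 1e-9

    def test_k_and_n_used(self):
        series = make_series(np.arange(6.0))
        joint = fit_model(series, "GRW", method="joint")
        assert (joint.K, joint.n_used) == (3, 6)
        ad = fit_model(series, "URW", method="ad")
        assert (ad.K, ad.n_used) == (1, 5)


class TestCompareModels:
    def test_weights_sum_to_one(self, rng):
        series = make_series(rng.normal(0, 1, 12))
        comp = compare_models(series)
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert min(comp.delta_aicc().values()) == 0.0

    def test_nestedness_grw_dominates_urw(self, rng):
        for _ in range(5):
            series = make_series(rng.normal(0, 1, 10))
            fg = fit_model(series, "GRW")
            fu = fit_model(series, "URW")
            assert fg.logL >= fu.logL - 1e-6

    def test_translation_invariance_of_ad_random_walks(self, rng):
        times = np.linspace(0.0, 2.0, 9)
        means = np.cumsum(rng.normal(0, 0.5, 9))
        a = make_series(means, times=times)
        b = make_series(means + 100.0, times=times)
        for model in ("URW", "GRW"):
            fa = fit_model(a, model, method="ad")
            fb = fit_model(b, model, method="ad")
            assert fa.logL == pytest.approx(fb.logL, abs=1e-8)

    def test_long_drift_series_strongly_supports_grw(self):
        wins = 0
        for s in spawn_seeds(33, 10):
            series, _ = build_series(
                BrownianDriftParams(5.0, 1.0),
                times=equidistant_times(2.0, 100),
                seed=s,
            )
            comp = compare_models(series)
            wins += comp.weights["GRW"] > 0.9
        assert wins >= 9

    def test_bit_reproducible(self):
        series, _ = build_series(
            BrownianDriftParams(0.0, 1.0), times=equidistant_times(2.0, 20), seed=5
        )
        w1 = compare_models(series).weights
        w2 = compare_models(series).weights
        assert w1 == w2


class TestEvidenceRatio:
    def test_ratio_of_weights(self):
        series = make_series([0.0, 0.1, 0.2, 0.15, 0.3])
        comp = compare_models(series)
        w = comp.weights
        assert evidence_ratio(comp, "URW", "GRW") == pytest.approx(
            w["URW"] / w["GRW"]
        )

    def test_equal_weights_unit_ratio(self):
        comp_like = type("C", (), {"weights": {"a": 0.5, "b": 0.5}})()
        assert evidence_ratio(comp_like, "a", "b") == 1.0

    def test_zero_denominator(self):
        comp_like = type("C", (), {"weights": {"a": 1.0, "b": 0.0}})()
        assert evidence_ratio(comp_like, "a", "b") == np.inf
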