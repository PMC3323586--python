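"""Model comparison and survival diagnostics: AICc arithmetic, Kaplan-Meier
identities, hazard shapes, Weibull probability plot and SSVS."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dentinsurv.diagnostics import (
    aicc,
    akaike_weights,
    empirical_hazard,
    kaplan_meier,
    ks_gof,
    predictor_correlations,
    score_models,
    ssvs,
    weibull_probability_plot,
)
from dentinsurv.synthetic import simulate_cohort, null_population
from dentinsurv.types import ValidationError


class TestAicc:
    def test_closed_formula(self):
        assert aicc(-100.0, 3, 30) == pytest.approx(200 + 6 + 24 / 26)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_zero_parameters(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_single_model(self):
        _, w = akaike_weights([123.4])
        assert w == pytest.approx([1.0])

    def test_two_equal_models(self):
        _, w = akaike_weights([100.0, 100.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_matches_direct_formula(self):
        delta, w = akaike_weights([200.0, 202.0, 210.0])
        raw = np.exp(-np.array([0.0, 2.0, 10.0]) / 2)
        np.testing.assert_allclose(w, raw / raw.sum())
        np.testing.assert_allclose(delta, [0, 2, 10])

    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=8),
           st.floats(-1000, 1000))
    def test_sum_one_and_shift_invariant(self, vals, shift):
        _, w1 = akaike_weights(vals)
        _, w2 = akaike_weights([v + shift for v in vals])
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w1, w2, atol=1e-9)


class TestKaplanMeier:
    def test_three_distinct_times(self):
        km = kaplan_meier([1.0, 2.0, 3.0])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_ties(self):
        km = kaplan_meier([2.0, 2.0, 5.0])
        assert km.survival[0] == pytest.approx(1 / 3)
        assert km.survival[-1] == pytest.approx(0.0)

    def test_equals_one_minus_ecdf(self, rng):
        t = rng.weibull(3, 1000) * 9
        km = kaplan_meier(t)
        ecdf = np.searchsorted(np.sort(t), km.times, side="right") / t.size
        np.testing.assert_allclose(km.survival, 1 - ecdf, atol=1e-12)

    def test_monotone_and_empty_error(self, rng):
        km = kaplan_meier(rng.weibull(3, 200) * 9)
        assert np.all(np.diff(km.survival) <= 0)
        with pytest.raises(ValidationError):
            kaplan_meier([])


class TestEmpiricalHazard:
    def test_single_death_over_unit_bin(self):
        # one death at the end of (0,1] with ten at risk: 1 / 10 person-years
        times = np.array([1.0] + [5.0] * 9)
        hz = empirical_hazard(times, bin_edges=np.array([0.0, 1.0, 6.0]))
        assert hz.hazard[0] == pytest.approx(0.1)

    def test_exponential_sample_is_flat(self, rng):
        t = rng.exponential(5.0, 5000)
        hz = empirical_hazard(t, bin_edges=np.arange(0.0, 11.0))
        interior = slice(0, 8)
        sm = hz.smoothed[interior]
        assert np.nanmax(np.abs(sm - 0.2)) / 0.2 < 0.15

    def test_weibull_hazard_increases(self, rng):
        t = rng.weibull(3, 5000) * 9
        lo, hi = np.quantile(t, [0.05, 0.90])
        hz = empirical_hazard(t)
        keep = (hz.bin_centers > lo) & (hz.bin_centers < hi) & np.isfinite(hz.smoothed)
        assert np.all(np.diff(hz.smoothed[keep]) > 0)

    def test_empty_bin_reported_missing(self):
        hz = empirical_hazard([5.0], bin_edges=np.array([0.0, 1.0, 6.0, 8.0]))
        assert np.isnan(hz.hazard[2])  # no person-time after death


class TestWeibullProbabilityPlot:
    def test_exact_quantile_grid(self):
        v, eta, n = 2.7, -5.0, 60
        s = 1 - np.arange(1, n + 1) / n
        t = (-np.log(s[:-1]) * math.exp(-eta)) ** (1 / v)
        wp = weibull_probability_plot(np.concatenate([t, [t.max() * 1.1]]))
        assert wp.r2 == pytest.approx(1.0, abs=1e-9)
        assert wp.slope == pytest.approx(v, abs=1e-9)

    def test_shape_recovery(self, rng):
        t = rng.weibull(3, 500) * 9
        wp = weibull_probability_plot(t)
        assert wp.slope == pytest.approx(3.0, rel=0.10)

    def test_exponential_slope_one(self, rng):
        t = rng.exponential(5.0, 500)
        wp = weibull_probability_plot(t)
        assert wp.slope == pytest.approx(1.0, rel=0.10)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            weibull_probability_plot([1.0, 2.0])


class TestKsGof:
    def test_identical_samples_d_zero(self, rng):
        x = rng.weibull(3, 100) * 9
        d, p = ks_gof(x, x)
        assert d == pytest.approx(0.0)

    def test_wrong_model_detected(self, rng):
        # halved shape changes the longevity distribution detectably
        obs = rng.weibull(3.0, 100) * 9
        pred = rng.weibull(1.5, 5000) * 9
        rejections = 0
        for _ in range(20):
            obs = rng.weibull(3.0, 100) * 9
            d, p = ks_gof(obs, pred)
            rejections += p < 0.01
        assert rejections >= 18


class TestPredictorCorrelations:
    def test_duplicated_column_perfect_correlation(self, rng):
        x = rng.normal(size=(50, 2))
        m = np.column_stack([x, x[:, 0]])
        corr = predictor_correlations(m)
        assert corr[0, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_independent_columns_near_zero(self, rng):
        corr = predictor_correlations(rng.normal(size=(10_000, 4)))
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(40, 3))
        corr = predictor_correlations(x)
        for i in range(3):
            for j in range(3):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                oracle = (xi * xj).sum() / math.sqrt((xi**2).sum() * (xj**2).sum())
                assert corr[i, j] == pytest.approx(oracle, abs=1e-12)


class TestSsvs:
    def test_zero_width_spike_degenerates_to_full_inclusion(self, quick_mcmc, rng):
        X = rng.normal(size=(30, 4))
        t = rng.weibull(3, 30) * 9
        incl, _ = ssvs(X, t, mcmc=quick_mcmc, seed=0, spike_scale=0.0)
        np.testing.assert_allclose(incl, 1.0)

    def test_selects_true_signal(self, quick_mcmc):
        cohort = simulate_cohort(100, seed=31)
        X = np.array([p.as_array() for p in cohort.individual_params])
        incl, _ = ssvs(X, cohort.longevities, mcmc=quick_mcmc, seed=32)
        assert incl[3] > 0.5  # the post-shift slope drives longevity
        assert incl[3] == max(incl)

    def test_null_truth_excludes_all(self, quick_mcmc):
        cohort = simulate_cohort(100, pop=null_population(), seed=33)
        X = np.array([p.as_array() for p in cohort.individual_params])
        incl, _ = ssvs(X, cohort.longevities, mcmc=quick_mcmc, seed=34)
        assert np.all(incl < 0.5)


class TestScoreModels:
    def test_table_structure(self, default_cohort, quick_mcmc):
        from dentinsurv.joint import fit_joint, fit_null

        fits = [fit_joint(default_cohort.series, mcmc=quick_mcmc, seed=1),
                fit_null(default_cohort.longevities, mcmc=quick_mcmc, seed=2)]
        table = score_models(fits)
        assert list(table.columns) == ["model", "K", "loglik", "AICc", "delta",
                                       "weight"]
        assert table["delta"].min() == pytest.approx(0.0)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
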