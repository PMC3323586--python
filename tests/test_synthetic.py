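"""Synthetic cohort generator: closed-form trajectory values, Weibull
moments, observation-grid structure and the dentin-record layer pattern."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dentinsurv.synthetic import (
    broken_stick_mean,
    default_population,
    draw_individual_params,
    simulate_dentin_records,
    simulate_longevity,
    simulate_series,
)
from dentinsurv.types import ChangePointParams, Context, PopulationParams, ValidationError

P = ChangePointParams(alpha=-20.0, tau=3.0, beta1=0.5, beta2=-0.4)


class TestBrokenStick:
    def test_closed_form_values(self):
        assert broken_stick_mean(1.0, P) == pytest.approx(-21.0)
        assert broken_stick_mean(5.0, P) == pytest.approx(-20.8)

    def test_value_at_knot_is_alpha(self):
        assert broken_stick_mean(P.tau, P) == pytest.approx(P.alpha)

    @given(st.floats(0, 20), st.floats(-2, 2), st.floats(0.1, 10),
           st.floats(-25, -15))
    def test_equal_slopes_collapse_to_line(self, age, b, tau, alpha):
        p = ChangePointParams(alpha=alpha, tau=tau, beta1=b, beta2=b)
        assert broken_stick_mean(age, p) == pytest.approx(alpha + b * (age - tau))

    @given(st.floats(0.2, 12))
    def test_continuity_at_knot(self, tau):
        p = ChangePointParams(alpha=-21.0, tau=tau, beta1=0.7, beta2=-0.5)
        eps = 1e-9
        left = broken_stick_mean(max(tau - eps, 0), p)
        right = broken_stick_mean(tau + eps, p)
        assert abs(left - right) < 1e-6


class TestIndividualParams:
    def test_degenerate_covariance_gives_means(self):
        pop = default_population()
        pop.sigma_re = np.zeros((4, 4))
        draws = draw_individual_params(pop, 5, seed=0)
        for d in draws:
            np.testing.assert_allclose(d.as_array(), pop.mu_re)

    def test_n_zero_gives_empty(self):
        assert draw_individual_params(default_population(), 0, seed=0) == []

    def test_variance_recovery(self):
        pop = default_population()
        pop.sigma_re = np.diag([1.0, 0.25, 0.04, 0.04])
        draws = draw_individual_params(pop, 100_000, seed=3)
        arr = np.array([d.as_array() for d in draws])
        for j, target in enumerate([1.0, 0.25, 0.04, 0.04]):
            assert arr[:, j].var() == pytest.approx(target, rel=0.05)

    def test_non_psd_covariance_rejected(self):
        pop = default_population()
        with pytest.raises(ValidationError):
            PopulationParams(mu_re=pop.mu_re, sigma_re=-np.eye(4),
                             sigma_obs=0.4, theta=pop.theta, shape=3.0)


class TestLongevity:
    def test_exponential_median(self):
        # v = 1, eta = 0 is a unit exponential: median ln 2
        t = simulate_longevity(P, np.zeros(5), 1.0, seed=0, size=1_000_000)
        # eta = theta0 = 0 only when all covariate effects vanish
        assert np.median(t) == pytest.approx(math.log(2), abs=0.005)

    @pytest.mark.parametrize("v,eta", [(0.8, -1.0), (1.0, 0.0), (3.0, -6.5)])
    def test_mean_matches_weibull_moment(self, v, eta):
        theta = np.array([eta, 0, 0, 0, 0])
        t = simulate_longevity(P, theta, v, seed=1, size=1_000_000)
        lam = math.exp(eta)
        expect = math.gamma(1 + 1 / v) * lam ** (-1 / v)
        assert t.mean() == pytest.approx(expect, rel=0.01)

    def test_negative_slope_effect_shortens_life(self):
        # theta_beta2 < 0 with beta2 < 0 raises eta, hastening death
        theta = np.array([-6.5, 0, 0, 0, -1.5])
        p_switch = ChangePointParams(alpha=-21, tau=2.5, beta1=0.6, beta2=-0.8)
        p_stable = ChangePointParams(alpha=-21, tau=2.5, beta1=0.6, beta2=0.0)
        t_sw = simulate_longevity(p_switch, theta, 3.0, seed=2, size=100_000)
        t_st = simulate_longevity(p_stable, theta, 3.0, seed=3, size=100_000)
        assert np.median(t_sw) < np.median(t_st)

    def test_null_theta_independent_of_trajectory(self):
        # with only an intercept, longevity carries no trajectory signal
        pop = default_population()
        pop.theta = np.array([-6.5, 0, 0, 0, 0])
        params = draw_individual_params(pop, 100_000, seed=4)
        rng = np.random.default_rng(5)
        beta2 = np.array([p.beta2 for p in params])
        t = np.array([simulate_longevity(p, pop.theta, pop.shape, rng)
                      for p in params])
        lo, hi = t[beta2 < np.median(beta2)], t[beta2 >= np.median(beta2)]
        assert stats.ks_2samp(lo, hi).pvalue > 0.01


class TestSeries:
    def test_noiseless_series_on_the_stick(self):
        s = simulate_series(P, 0.0, 6.0, 4, seed=0)
        np.testing.assert_allclose(s.values, broken_stick_mean(s.ages, P))

    def test_quarter_year_grid_count(self):
        s = simulate_series(P, 0.4, 2.0, 4, seed=0)
        assert len(s) == 8
        assert s.ages[0] == pytest.approx(0.25)
        assert s.ages[-1] <= s.longevity

    def test_residual_sd_recovery(self):
        sds = []
        for seed in range(50):
            s = simulate_series(P, 0.4, 500.0, 4, seed=seed)
            sds.append(s.values - broken_stick_mean(s.ages, P))
        pooled = np.concatenate(sds)
        assert pooled.size >= 100_000
        assert pooled.std() == pytest.approx(0.4, rel=0.02)


class TestDentinRecords:
    def test_annual_context_pattern(self):
        s = simulate_series(P, 0.0, 2.0, 4, seed=0)
        recs = simulate_dentin_records(s, 0.0, (2.9, 3.6), seed=0)
        pattern = [r.context for r in recs]
        assert pattern == [Context.ASHORE, Context.ASHORE, Context.AT_SEA,
                           Context.AT_SEA] * 2

    def test_no_alteration_all_pass(self):
        s = simulate_series(P, 0.0, 10.0, 4, seed=0)
        recs = simulate_dentin_records(s, 0.0, (2.9, 3.6), seed=0)
        assert all(2.9 <= r.cn_ratio <= 3.6 for r in recs)

    def test_alteration_fraction_binomial(self):
        s = simulate_series(P, 0.0, 250.0, 4, seed=0)
        recs = simulate_dentin_records(s, 0.5, (2.9, 3.6), seed=1)
        n_bad = sum(not (2.9 <= r.cn_ratio <= 3.6) for r in recs)
        n = len(recs)
        assert n == 1000
        # 4 sigma binomial band around 500
        assert abs(n_bad - 500) < 4 * math.sqrt(1000 * 0.25)

    def test_cohort_respects_longevity(self, default_cohort):
        for s in default_cohort.series:
            assert s.ages[-1] <= s.longevity
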