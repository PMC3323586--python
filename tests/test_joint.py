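"""Joint change-point/Weibull-AFT model: likelihood oracles, Weibull
identities, and recovery behaviour of the null/competitor fits."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from dentinsurv.joint import (
    changepoint_loglik,
    fit_joint,
    fit_mixture_aft,
    fit_null,
    fit_random,
    total_loglik,
    weibull_aft_logpdf,
    weibull_hazard,
    weibull_survival,
)
from dentinsurv.synthetic import (
    broken_stick_mean,
    default_population,
    simulate_cohort,
    simulate_series,
)
from dentinsurv.types import ChangePointParams, IsotopeSeries, ValidationError

P = ChangePointParams(alpha=-21.0, tau=2.5, beta1=0.6, beta2=-0.3)


class TestChangepointLoglik:
    def test_zero_residuals_unit_sigma(self):
        s = simulate_series(P, 0.0, 5.0, 4, seed=0)
        n = len(s)
        assert changepoint_loglik(s, P, 1.0) == pytest.approx(-n / 2 * math.log(2 * math.pi))

    def test_matches_per_point_oracle(self, rng):
        ages = np.sort(rng.uniform(0.25, 7.5, 30))
        vals = rng.normal(-21, 1.0, 30)
        s = IsotopeSeries("x", ages, vals, longevity=8.0)
        resid = vals - broken_stick_mean(ages, P)
        oracle = stats.norm.logpdf(resid, scale=0.4).sum()
        assert changepoint_loglik(s, P, 0.4) == pytest.approx(oracle, rel=1e-12)

    def test_doubling_sigma_scale_property(self):
        s = simulate_series(P, 0.0, 5.0, 4, seed=0)
        n = len(s)
        diff = changepoint_loglik(s, P, 1.0) - changepoint_loglik(s, P, 2.0)
        assert diff == pytest.approx(n * math.log(2))


class TestWeibullAft:
    def test_unit_exponential_density(self):
        assert weibull_aft_logpdf(1.0, 0.0, 1.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("v", [0.5, 1.0, 3.0])
    @pytest.mark.parametrize("eta", [-2.0, 0.0])
    def test_density_integrates_to_one(self, v, eta):
        val, err = integrate.quad(lambda t: math.exp(weibull_aft_logpdf(t, eta, v)),
                                  0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("v,eta,t", [(0.5, -2, 0.3), (1, 0, 1.7), (3, -6.5, 8.0)])
    def test_hazard_survival_identities(self, v, eta, t):
        f = math.exp(weibull_aft_logpdf(t, eta, v))
        h, s = weibull_hazard(t, eta, v), weibull_survival(t, eta, v)
        assert abs(f - h * s) < 1e-12
        assert abs(-math.log(s) - math.exp(eta) * t**v) < 1e-12

    def test_hazard_monotone_increasing_for_v_gt_1(self):
        t = np.linspace(0.5, 15, 100)
        h = weibull_hazard(t, -6.5, 3.0)
        assert np.all(np.diff(h) > 0)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            weibull_aft_logpdf(-1.0, 0.0, 1.0)
        with pytest.raises(ValidationError):
            weibull_survival(1.0, 0.0, -2.0)

    def test_positive_coefficient_hastens_death(self):
        # AFT sign convention: larger eta => smaller median survival time
        med = lambda eta: (math.log(2) * math.exp(-eta)) ** (1 / 3.0)
        assert med(-6.0) < med(-6.5) < med(-7.0)


class TestTotalLoglik:
    def test_zero_data_is_zero(self):
        assert total_loglik(np.array([]), np.array([]), 3.0) == 0.0

    def test_additive_over_individuals(self, rng):
        t = rng.uniform(2, 12, 6)
        eta = rng.normal(-6.5, 0.3, 6)
        whole = total_loglik(t, eta, 3.0)
        parts = sum(total_loglik(t[i:i + 1], eta[i:i + 1], 3.0) for i in range(6))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_matches_scipy_weibull_oracle(self, rng):
        # independent parameterization: weibull_min(c=v, scale=exp(-eta/v))
        t = rng.uniform(2, 12, 5)
        eta, v = -6.5, 3.0
        oracle = stats.weibull_min.logpdf(t, c=v, scale=math.exp(-eta / v)).sum()
        assert total_loglik(t, eta, v) == pytest.approx(oracle, rel=1e-10)

    def test_longitudinal_term_added(self):
        s = simulate_series(P, 0.0, 4.0, 4, seed=0)
        base = total_loglik(np.array([4.0]), np.array([-6.5]), 3.0)
        both = total_loglik(np.array([4.0]), np.array([-6.5]), 3.0,
                            series_list=[s], cp_params=[P], sigma_obs=0.4)
        assert both == pytest.approx(base + changepoint_loglik(s, P, 0.4))


class TestFitNull:
    def test_shape_recovery(self, quick_mcmc, rng):
        t = (rng.exponential(size=1000) * math.exp(6.5)) ** (1 / 3.0)
        fit = fit_null(t, mcmc=quick_mcmc, seed=11)
        assert fit.median("v") == pytest.approx(3.0, rel=0.10)
        # posterior-predictive median vs the closed form lambda^(-1/v)(ln2)^(1/v)
        v_hat, th0_hat = fit.median("v"), fit.median("theta0")
        med_closed = (math.log(2) * math.exp(-th0_hat)) ** (1 / v_hat)
        assert med_closed == pytest.approx(np.median(t), rel=0.05)

    def test_tiny_sample_runs(self, quick_mcmc):
        fit = fit_null(np.array([4.0, 9.0]), mcmc=quick_mcmc, seed=1)
        lo, hi = fit.interval("v")
        assert hi - lo > 1.0  # wide, but no crash

    def test_rejects_empty_and_nonpositive(self, quick_mcmc):
        with pytest.raises(ValidationError):
            fit_null(np.array([]), mcmc=quick_mcmc)
        with pytest.raises(ValidationError):
            fit_null(np.array([1.0, -2.0]), mcmc=quick_mcmc)


class TestFitMixtureAft:
    def test_group_recode_symmetry_exact_in_likelihood(self):
        # eta(theta0, tg; g) == eta(theta0 + tg, -tg; 1 - g) identically
        g = np.array([0, 1, 1, 0, 1.0])
        t = np.array([5.0, 3.0, 4.0, 8.0, 2.5])
        th0, tg, v = -6.0, 0.8, 2.5
        a = total_loglik(t, th0 + tg * g, v)
        b = total_loglik(t, (th0 + tg) + (-tg) * (1 - g), v)
        assert a == pytest.approx(b, rel=1e-14)

    def test_group_recode_flips_posterior_sign(self, quick_mcmc, rng):
        t = np.concatenate([rng.weibull(3, 40) * 9, rng.weibull(3, 40) * 6])
        g = np.repeat([0, 1], 40)
        f1 = fit_mixture_aft(t, g, mcmc=quick_mcmc, seed=3)
        f2 = fit_mixture_aft(t, 1 - g, mcmc=quick_mcmc, seed=3)
        assert f1.median("theta_group") > 0  # group 1 dies earlier
        assert f2.median("theta_group") == pytest.approx(
            -f1.median("theta_group"), abs=3 * f1.stacked("theta_group").std())

    def test_single_group_rejected(self, quick_mcmc):
        with pytest.raises(ValidationError):
            fit_mixture_aft(np.array([3.0, 4.0]), np.array([1, 1]), mcmc=quick_mcmc)


class TestFitRandom:
    def test_runs_and_scores(self, default_cohort, quick_mcmc):
        fit = fit_random(default_cohort.series, mcmc=quick_mcmc, seed=5)
        assert fit.extra["K"] == 3
        assert np.isfinite(fit.extra["loglik"])
        assert np.all(fit.stacked("v") > 0)


class TestFitJoint:
    def test_noiseless_limit_recovers_individuals(self, quick_mcmc):
        pop = default_population()
        pop.sigma_obs = 1e-3
        cohort = simulate_cohort(12, pop=pop, seed=21)
        fit = fit_joint(cohort.series, mcmc=quick_mcmc, seed=22)
        checked = 0
        for s, p in zip(cohort.series, cohort.individual_params):
            # a change-point outside the observed age span leaves (alpha, tau)
            # on an unidentified ridge even without noise; skip those seals
            if not (s.ages[0] + 0.25 < p.tau < s.ages[-1] - 0.5):
                continue
            checked += 1
            for name, truth in zip(("alpha", "tau", "beta1", "beta2"),
                                   p.as_array()):
                est = fit.mean(f"{name}[{s.individual_id}]")
                assert est == pytest.approx(truth, abs=0.05), (
                    f"{name} for {s.individual_id}")
        assert checked >= 8

    def test_covariance_draws_valid(self, default_cohort, quick_mcmc):
        fit = fit_joint(default_cohort.series, mcmc=quick_mcmc, seed=9)
        assert np.all(fit.stacked("v") > 0)
        for name in ("alpha", "tau", "beta1", "beta2"):
            assert np.all(fit.stacked(f"Sigma[{name},{name}]") > 0)
        # every reported scalar carries an R-hat
        assert set(fit.rhat) == set(fit.reported)

    def test_covariate_subset(self, default_cohort, quick_mcmc):
        fit = fit_joint(default_cohort.series, mcmc=quick_mcmc, seed=10,
                        covariates=("beta2",))
        assert fit.extra["K"] == 3
        assert "theta_beta2" in fit.params and "theta_alpha" not in fit.params
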