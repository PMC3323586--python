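"""Model comparison and survival diagnostics.

AICc model selection with Akaike weights; Kaplan-Meier survival with
Greenwood confidence bands; binned empirical hazard with a locally weighted
smoother; the Weibull probability plot (log t versus log(−log S) should be a
straight line of slope v); posterior-predictive Kolmogorov-Smirnov
goodness-of-fit; correlations between the per-individual trajectory
parameters used as survival predictors; and stochastic search variable
selection over the AFT covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .joint import JointPriors, _weibull_ll_sum
from .mcmc import AdaptiveRW, McmcConfig, PosteriorDraws, mh_accept, student_t_logpdf
from .types import KMCurve, ModelScore, ValidationError

logger = logging.getLogger(__name__)


# ------------------------------------------------------------ model selection


def aicc(loglik: float, K: int, n: int) -> float:
    """Akaike Information Criterion with small-sample correction:
    −2 log L + 2K + 2K(K+1)/(n − K − 1).  Undefined for n <= K + 1."""
    if n <= K + 1:
        raise ValidationError(f"AICc undefined for n={n}, K={K} (need n > K + 1)")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """Return (delta, weight): Δ_m = AICc_m − min AICc and
    w_m = exp(−Δ_m/2) / Σ exp(−Δ/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValidationError("need at least one AICc value")
    delta = a - a.min()
    raw = np.exp(-delta / 2.0)
    return delta, raw / raw.sum()


def score_models(fits: list[PosteriorDraws]) -> pd.DataFrame:
    """Build the AFT model-comparison table from fitted models.

    Log-likelihoods are the Weibull survival log-likelihood at posterior
    means and K counts the AFT parameters (intercept + covariate
    coefficients + shape); the longitudinal submodels only supply the
    covariates, so the four models are scored on the same data.
    """
    n_set = {f.extra["n"] for f in fits}
    if len(n_set) != 1:
        raise ValidationError("models were fitted to different numbers of individuals")
    n = n_set.pop()
    scores = [
        ModelScore(name=f.extra["model"], K=f.extra["K"], loglik=f.extra["loglik"],
                   aicc=aicc(f.extra["loglik"], f.extra["K"], n))
        for f in fits
    ]
    delta, weight = akaike_weights([s.aicc for s in scores])
    for s, d, w in zip(scores, delta, weight):
        s.delta, s.weight = float(d), float(w)
    df = pd.DataFrame(
        [{"model": s.name, "K": s.K, "loglik": s.loglik, "AICc": s.aicc,
          "delta": s.delta, "weight": s.weight} for s in scores]
    ).sort_values("AICc", ignore_index=True)
    return df


# ------------------------------------------------------------------- survival


def kaplan_meier(times, alpha: float = 0.05) -> KMCurve:
    """Product-limit survival estimate with Greenwood-type pointwise CI.

    No censoring is supported (all tooth donors were found dead), so the
    estimate equals 1 − ECDF and ends at zero.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("empty survival data")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times)
    uniq = np.unique(times)
    surv = kmf.survival_function_at_times(uniq).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(uniq, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(uniq, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    return KMCurve(times=uniq, survival=surv, ci_lower=lo, ci_upper=hi)


@dataclass
class HazardEstimate:
    """Binned deaths / person-time-at-risk, plus a lowess smooth."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    hazard: np.ndarray  # NaN where no person-time (undefined, not zero)
    at_risk: np.ndarray  # individuals alive at the bin start
    smoothed: np.ndarray  # NaN where the raw hazard is undefined


def empirical_hazard(times, bin_edges=None, span: float = 0.75) -> HazardEstimate:
    """Empirical hazard per age bin with a locally weighted (lowess) smooth.

    The raw hazard in a bin is deaths / person-time at risk; bins with no
    person-time are reported missing.  Uncertainty grows with age as the
    risk set shrinks (``at_risk`` lets callers display that).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("empty survival data")
    if bin_edges is None:
        bin_edges = np.arange(0.0, np.ceil(times.max()) + 1.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    lo, hi = bin_edges[:-1], bin_edges[1:]
    # deaths counted in (a, b]; person-time is the time alive spent inside it
    deaths = np.array([((times > a) & (times <= b)).sum() for a, b in zip(lo, hi)],
                      dtype=float)
    persontime = np.array(
        [np.sum(np.clip(times, a, b) - a) for a, b in zip(lo, hi)]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        hazard = np.where(persontime > 0, deaths / persontime, np.nan)
    centers = (lo + hi) / 2.0
    ok = np.isfinite(hazard)
    smoothed = np.full_like(hazard, np.nan)
    if ok.sum() >= 3:
        sm = lowess(hazard[ok], centers[ok], frac=span, return_sorted=False)
        smoothed[ok] = sm
    at_risk = np.array([(times >= a).sum() for a in lo], dtype=float)
    return HazardEstimate(bin_edges=bin_edges, bin_centers=centers, hazard=hazard,
                          at_risk=at_risk, smoothed=smoothed)


@dataclass
class WeibullPlot:
    """Points of the Weibull probability plot and its least-squares line.
    Under a Weibull law, log(−log S(t)) = η + v log t, so the slope
    estimates the shape v and R² measures straightness."""

    log_t: np.ndarray
    log_neg_log_s: np.ndarray
    slope: float
    intercept: float
    r2: float


def weibull_probability_plot(times) -> WeibullPlot:
    """Plot log(−log S_KM) against log t and fit a line; the final point
    where S_KM = 0 is excluded (its log is undefined)."""
    km = kaplan_meier(times)
    keep = km.survival > 0
    t, s = km.times[keep], km.survival[keep]
    if t.size < 3:
        raise ValidationError("need at least 3 usable points for the Weibull plot")
    x = np.log(t)
    y = np.log(-np.log(s))
    res = sps.linregress(x, y)
    return WeibullPlot(log_t=x, log_neg_log_s=y, slope=float(res.slope),
                       intercept=float(res.intercept), r2=float(res.rvalue**2))


def ks_gof(observed, predicted) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of observed longevities with
    a (large) posterior-predictive sample."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0 or predicted.size == 0:
        raise ValidationError("empty sample")
    res = sps.ks_2samp(observed, predicted, method="asymp")
    return float(res.statistic), float(res.pvalue)


def posterior_predictive_longevities(
    fit: PosteriorDraws, n_per_draw: int = 1, seed: int = 0, max_draws: int = 2000
) -> np.ndarray:
    """Sample longevities from the fitted AFT posterior: for each retained
    draw, new individuals inherit the posterior-mean linear predictors."""
    rng = np.random.default_rng(seed)
    eta_hat = np.asarray(fit.extra["eta_hat"], dtype=float)
    v_draws = fit.stacked("v")
    take = rng.choice(v_draws.size, size=min(max_draws, v_draws.size), replace=False)
    out = []
    for k in take:
        v = v_draws[k]
        eta = rng.choice(eta_hat, size=n_per_draw)
        e = rng.exponential(size=n_per_draw)
        out.append((e * np.exp(-eta)) ** (1.0 / v))
    return np.concatenate(out)


# ------------------------------------------------------------------ predictors


def predictor_correlations(param_matrix) -> np.ndarray:
    """Correlation matrix of the per-individual posterior-mean trajectory
    parameters (columns alpha, tau, beta1, beta2)."""
    x = np.asarray(param_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValidationError("need a (n >= 3, p) matrix")
    return np.corrcoef(x, rowvar=False)


# ------------------------------------------------------------------------ SSVS


def ssvs(
    covariates,
    longevities,
    priors: JointPriors | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    slab_scale: float = 2.5,
    spike_scale: float = 0.025,
    inclusion_prior: float = 0.5,
) -> tuple[np.ndarray, PosteriorDraws]:
    """Stochastic search variable selection over the AFT covariates.

    Continuous spike-and-slab: θ_j ~ γ_j N(0, slab²) + (1−γ_j) N(0, spike²),
    γ_j ~ Bernoulli(inclusion_prior), on internally standardized covariates.
    Moves between spike and slab are joint (γ_j, θ_j) proposals where θ_j is
    redrawn from a pilot-posterior approximation, which avoids the sticking
    that plagues within-state-only updates.  Returns posterior inclusion
    probabilities per covariate and the underlying draws.

    A zero-width spike degenerates to every covariate always included.
    """
    priors = priors or JointPriors()
    mcmc = mcmc or McmcConfig()
    X = np.asarray(covariates, dtype=float)
    T = np.asarray(longevities, dtype=float)
    if X.ndim != 2 or X.shape[0] != T.size:
        raise ValidationError("covariates must be (n, p) matching longevities")
    n, p = X.shape
    if spike_scale == 0:
        ones = np.ones(p)
        logger.info("zero-width spike: every covariate is always included")
        dummy = PosteriorDraws(params={"gamma_sum": np.full((mcmc.chains, 2), float(p))},
                               warmup=0, thin=1)
        return ones, dummy

    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("constant covariate column")
    Xs = (X - X.mean(axis=0)) / sd
    logT = np.log(T)
    v_lo, v_hi = priors.v_bounds

    # pilot slab-only fit → independence-proposal centers/scales per coefficient
    from .joint import _fit_aft_block  # local import to avoid cycle at module load

    pilot = _fit_aft_block(T, Xs, ["theta0"] + [f"c{j}" for j in range(p)],
                           priors, McmcConfig(chains=2, warmup=400, draws=400),
                           seed=seed + 1, model_name="ssvs_pilot")
    prop_mean = np.array([pilot.mean(f"c{j}") for j in range(p)])
    prop_sd = np.array([np.std(pilot.stacked(f"c{j}")) for j in range(p)])
    prop_sd = np.maximum(prop_sd, 1e-3)

    def norm_logpdf(x, loc, scale):
        return (-0.5 * ((x - loc) / scale) ** 2 - np.log(scale)
                - 0.5 * math.log(2 * math.pi))

    log_prior_odds = math.log(inclusion_prior) - math.log1p(-inclusion_prior)

    chains_gamma, chains_theta = [], []
    for child in np.random.SeedSequence(seed).spawn(mcmc.chains):
        rng = np.random.default_rng(child)
        gamma = rng.random(p) < inclusion_prior
        theta = np.where(gamma, prop_mean, 0.0) + rng.normal(0, 0.1, p)
        th0 = pilot.mean("theta0") + rng.normal(0, 0.5)
        logv = math.log(pilot.mean("v")) + rng.normal(0, 0.2)
        rw = AdaptiveRW(p + 2, scale=0.2)

        def loglik(th0_, theta_, logv_):
            v_ = math.exp(logv_)
            if not (v_lo < v_ < v_hi):
                return -np.inf
            return _weibull_ll_sum(T, logT, th0_ + Xs @ theta_, v_)

        def theta_logprior(theta_, gamma_):
            scales = np.where(gamma_, slab_scale, spike_scale)
            return float(np.sum(norm_logpdf(theta_, 0.0, scales)))

        n_iter = mcmc.warmup + mcmc.draws * mcmc.thin
        g_out = np.empty((mcmc.draws, p))
        t_out = np.empty((mcmc.draws, p + 2))
        k = 0
        for it in range(n_iter):
            if it == mcmc.warmup:
                rw.freeze()
            # within-state block update of all continuous parameters
            phi = np.concatenate([[th0], theta, [logv]])
            lp_cur = (loglik(th0, theta, logv) + theta_logprior(theta, gamma)
                      + float(student_t_logpdf(th0, priors.theta_df, 0, priors.theta0_scale))
                      + logv)
            for _ in range(3):
                prop = rw.propose(phi, rng)
                lp_p = (loglik(prop[0], prop[1:-1], prop[-1])
                        + theta_logprior(prop[1:-1], gamma)
                        + float(student_t_logpdf(prop[0], priors.theta_df, 0,
                                                 priors.theta0_scale))
                        + prop[-1])
                if mh_accept(lp_p - lp_cur, rng):
                    phi, lp_cur = prop, lp_p
                    rw.adapt(True)
                else:
                    rw.adapt(False)
                rw.update_state(phi)
            th0, theta, logv = float(phi[0]), phi[1:-1].copy(), float(phi[-1])
            # between-state flips: joint (gamma_j, theta_j) proposal
            for j in range(p):
                g_new = not gamma[j]
                if g_new:
                    t_new = rng.normal(prop_mean[j], prop_sd[j])
                    q_fwd = norm_logpdf(t_new, prop_mean[j], prop_sd[j])
                    q_rev = norm_logpdf(theta[j], 0.0, spike_scale)
                    d_prior = log_prior_odds
                else:
                    t_new = rng.normal(0.0, spike_scale)
                    q_fwd = norm_logpdf(t_new, 0.0, spike_scale)
                    q_rev = norm_logpdf(theta[j], prop_mean[j], prop_sd[j])
                    d_prior = -log_prior_odds
                theta_prop = theta.copy()
                theta_prop[j] = t_new
                d = (
                    loglik(th0, theta_prop, logv) - loglik(th0, theta, logv)
                    + norm_logpdf(t_new, 0.0, slab_scale if g_new else spike_scale)
                    - norm_logpdf(theta[j], 0.0, slab_scale if gamma[j] else spike_scale)
                    + d_prior + q_rev - q_fwd
                )
                if mh_accept(d, rng):
                    gamma[j] = g_new
                    theta = theta_prop
            if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
                g_out[k] = gamma
                t_out[k] = np.concatenate([[th0], theta, [logv]])
                k += 1
        chains_gamma.append(g_out)
        chains_theta.append(t_out)

    g = np.stack(chains_gamma)  # (chains, draws, p)
    t_arr = np.stack(chains_theta)
    params = {f"gamma{j}": g[:, :, j] for j in range(p)}
    params.update({f"theta{j}": t_arr[:, :, j + 1] for j in range(p)})
    params["theta0"] = t_arr[:, :, 0]
    params["v"] = np.exp(t_arr[:, :, -1])
    draws = PosteriorDraws(params=params, warmup=mcmc.warmup, thin=mcmc.thin,
                           reported=["theta0", "v"])
    inclusion = g.reshape(-1, p).mean(axis=0)
    return inclusion, draws
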