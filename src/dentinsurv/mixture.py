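"""Two-component growth mixture model of δ¹³C versus age.

A descriptive model of the cohort: each individual belongs for life to one
of two latent foraging strategies — Subantarctic (component 1, higher δ¹³C)
or Antarctic (component 2, lower δ¹³C) — and its observations scatter around
that component's per-age-class mean curve.  Identification constraints are
built into the sampler rather than imposed by rejection:

* ordering: mu2(t) < mu1(t) at every age class, because the Antarctic
  signature is isotopically lighter, which removes label switching;
* isotonicity: mu1 is non-decreasing and mu2 non-increasing in age
  (each strategy equilibrates monotonically toward its habitat signature).

Both constraints are enforced by construction inside the sampler: each
per-age-class curve value is drawn from its exact full conditional — a
Normal truncated to the interval its neighbours and the opposing curve
allow — so every retained posterior draw satisfies ordering and isotonicity
exactly, with no rejection step.  Observations are pooled into integer-year
age classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .mcmc import (
    McmcConfig,
    PosteriorDraws,
    truncated_invgamma_sd,
    truncnorm_draw,
)
from .types import IsotopeSeries, ValidationError

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class MixturePriors:
    """Beta(2,2) on the mixing proportion; uniform on the residual SD;
    weakly-informative Normal on each natural-scale curve value (truncated
    in the sampler to the region the ordering/isotonicity constraints
    allow)."""

    w_a: float = 2.0
    w_b: float = 2.0
    sigma_upper: float = 10.0
    level_loc: float = -20.0
    level_scale: float = 10.0


@dataclass
class MixtureFit:
    """Posterior of the two-component growth mixture.

    ``draws`` holds (chains, draws) arrays for w, sigma_m and every
    mu1[t]/mu2[t]; ``class_prob`` is each individual's (Rao-Blackwellized)
    posterior probability of belonging to component 1.
    """

    age_classes: np.ndarray
    draws: PosteriorDraws
    class_prob: np.ndarray
    individual_ids: list[str]

    @property
    def converged(self) -> bool:
        return self.draws.converged

    def curve(self, component: int, stat=np.mean) -> np.ndarray:
        return np.array(
            [stat(self.draws.stacked(f"mu{component}[{t}]")) for t in self.age_classes]
        )

    @property
    def w(self) -> float:
        return self.draws.mean("w")

    @property
    def sigma_m(self) -> float:
        return self.draws.mean("sigma_m")

    def hard_assignment(self, threshold: float = 0.5) -> np.ndarray:
        """1 where component 1 (Subantarctic) is more probable than
        ``threshold``, else 2."""
        return np.where(self.class_prob >= threshold, 1, 2)


def _age_class_index(ages: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer-year pooling: class t covers ages (t-1, t]."""
    return np.minimum(np.ceil(ages - 1e-9).astype(int), n_classes) - 1


class _MixData:
    def __init__(self, series_list: list[IsotopeSeries], n_classes: int | None = None,
                 min_individuals: int = 1):
        if len(series_list) < min_individuals:
            raise ValidationError(f"need at least {min_individuals} individuals")
        self.n = len(series_list)
        self.ids = [s.individual_id for s in series_list]
        max_age = max(float(s.ages.max()) for s in series_list)
        self.n_classes = n_classes or int(np.ceil(max_age - 1e-9))
        self.y = np.concatenate([s.values for s in series_list])
        ages = np.concatenate([s.ages for s in series_list])
        if ages.max() > self.n_classes + 1e-9:
            raise ValidationError("observation age outside the fitted age-class grid")
        self.cls = _age_class_index(ages, self.n_classes)
        self.idx = np.concatenate(
            [np.full(len(s), i, dtype=np.intp) for i, s in enumerate(series_list)]
        )
        self.counts = np.bincount(self.idx, minlength=self.n).astype(float)
        self.counts_cls = np.bincount(self.cls, minlength=self.n_classes).astype(float)
        self.sums_cls = np.bincount(self.cls, weights=self.y, minlength=self.n_classes)
        self.m = self.y.size

    def per_individual_ll(self, mu: np.ndarray, sigma: float) -> np.ndarray:
        """Log-likelihood of each individual's data under one component curve."""
        resid = self.y - mu[self.cls]
        ll_pt = -0.5 * (resid / sigma) ** 2
        return (
            np.bincount(self.idx, weights=ll_pt, minlength=self.n)
            - self.counts * (math.log(sigma) + 0.5 * _LOG_2PI)
        )


def responsibilities(
    data_ll1: np.ndarray, data_ll2: np.ndarray, w: float
) -> np.ndarray:
    """P(component 1 | data, curves, w) per individual."""
    a = np.log(w) + data_ll1
    b = np.log1p(-w) + data_ll2
    return np.exp(a - np.logaddexp(a, b))


def fit_growth_mixture(
    series_list: list[IsotopeSeries],
    age_classes: int | None = None,
    priors: MixturePriors | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> MixtureFit:
    """Fit the constrained two-component growth mixture by blocked Gibbs:
    latent classes and the mixing proportion are exact conditional draws,
    the residual SD a truncated inverse-gamma draw, and the curve
    parameters one adaptive Metropolis block."""
    priors = priors or MixturePriors()
    mcmc = mcmc or McmcConfig()
    data = _MixData(series_list, age_classes, min_individuals=2)
    T = data.n_classes
    if T < 2:
        raise ValidationError("need at least 2 age classes")

    ybar_i = np.bincount(data.idx, weights=data.y, minlength=data.n) / data.counts
    split = float(np.median(ybar_i))
    prior_prec = 1.0 / priors.level_scale**2

    chain_stores = []
    resp_accum = np.zeros(data.n)
    resp_count = 0
    for c, child in enumerate(np.random.SeedSequence(seed).spawn(mcmc.chains)):
        rng = np.random.default_rng(child)
        # overdispersed inits around a median split of individual means,
        # projected onto the constraint set
        hi = ybar_i >= split
        lev1 = float(np.mean(data.y[hi[data.idx]])) if hi.any() else float(np.mean(data.y))
        lev2 = float(np.mean(data.y[~hi[data.idx]])) if (~hi).any() else lev1 - 1.0
        mu1 = np.full(T, lev1) + rng.normal(0, 0.3)
        mu2 = np.full(T, min(lev2, lev1 - 0.5)) + rng.normal(0, 0.3)
        mu2 = np.minimum(mu2, mu1 - 0.1)
        sigma = float(np.std(data.y)) * 0.5 * math.exp(rng.normal(0, 0.3)) + 1e-3
        w = float(rng.beta(priors.w_a, priors.w_b))

        n_iter = mcmc.warmup + mcmc.draws * mcmc.thin
        store: dict[str, list] = {}
        for it in range(n_iter):
            ll1 = data.per_individual_ll(mu1, sigma)
            ll2 = data.per_individual_ll(mu2, sigma)
            # 1. latent classes (exact) — Rao-Blackwellized probabilities kept
            p1 = responsibilities(ll1, ll2, w)
            z1 = rng.random(data.n) < p1
            # 2. mixing proportion (conjugate beta)
            n1 = int(z1.sum())
            w = float(rng.beta(priors.w_a + n1, priors.w_b + data.n - n1))
            # 3. residual SD
            mu_z = np.where(z1[data.idx], mu1[data.cls], mu2[data.cls])
            ss = float(np.sum((data.y - mu_z) ** 2))
            sigma = truncated_invgamma_sd(ss, data.m, priors.sigma_upper, rng)
            # 4. curve values: exact truncated-normal Gibbs under the
            # ordering and isotonicity constraints
            obs_z1 = z1[data.idx]
            w_obs = obs_z1.astype(float)
            n1_t = np.bincount(data.cls, weights=w_obs, minlength=T)
            s1_t = np.bincount(data.cls, weights=data.y * w_obs, minlength=T)
            n2_t = data.counts_cls - n1_t
            s2_t = data.sums_cls - s1_t
            prec1 = n1_t / sigma**2 + prior_prec
            mean1 = (s1_t / sigma**2 + priors.level_loc * prior_prec) / prec1
            prec2 = n2_t / sigma**2 + prior_prec
            mean2 = (s2_t / sigma**2 + priors.level_loc * prior_prec) / prec2
            for t in range(T):  # mu1 non-decreasing, above mu2
                lo = max(mu1[t - 1] if t > 0 else -np.inf, mu2[t])
                up = mu1[t + 1] if t < T - 1 else np.inf
                mu1[t] = truncnorm_draw(mean1[t], 1 / math.sqrt(prec1[t]), lo, up, rng)
            for t in range(T - 1, -1, -1):  # mu2 non-increasing, below mu1
                lo = mu2[t + 1] if t < T - 1 else -np.inf
                up = min(mu2[t - 1] if t > 0 else np.inf, mu1[t])
                mu2[t] = truncnorm_draw(mean2[t], 1 / math.sqrt(prec2[t]), lo, up, rng)
            if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
                store.setdefault("w", []).append(w)
                store.setdefault("sigma_m", []).append(sigma)
                for t in range(T):
                    store.setdefault(f"mu1[{t + 1}]", []).append(float(mu1[t]))
                    store.setdefault(f"mu2[{t + 1}]", []).append(float(mu2[t]))
                resp_accum += responsibilities(
                    data.per_individual_ll(mu1, sigma),
                    data.per_individual_ll(mu2, sigma), w,
                )
                resp_count += 1
        chain_stores.append({k: np.array(vv) for k, vv in store.items()})

    params = {k: np.stack([ch[k] for ch in chain_stores]) for k in chain_stores[0]}
    draws = PosteriorDraws(params=params, warmup=mcmc.warmup, thin=mcmc.thin)
    if not draws.converged:
        logger.warning("growth mixture: R-hat >= 1.1 for %s",
                       [k for k, r in draws.rhat.items() if not (np.isnan(r) or r < 1.1)])
    return MixtureFit(
        age_classes=np.arange(1, T + 1),
        draws=draws,
        class_prob=resp_accum / resp_count,
        individual_ids=data.ids,
    )


def mixture_loglik(
    series_list: list[IsotopeSeries],
    mu1: np.ndarray,
    mu2: np.ndarray,
    w: float,
    sigma: float,
) -> float:
    """Observed-data log-likelihood with the latent class marginalized per
    individual: Σ_i log[ w Π_j N(y_ij; mu1) + (1−w) Π_j N(y_ij; mu2) ]."""
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    if not 0 <= w <= 1:
        raise ValidationError("mixing proportion must lie in [0, 1]")
    data = _MixData(series_list, n_classes=mu1.size)
    ll1 = data.per_individual_ll(mu1, sigma)
    ll2 = data.per_individual_ll(mu2, sigma)
    with np.errstate(divide="ignore"):
        per_ind = logsumexp(
            np.stack([np.log(w) + ll1, np.log1p(-w) + ll2]), axis=0
        )
    return float(np.sum(per_ind))


def mixture_loglik_from_fit(series_list: list[IsotopeSeries], fit: MixtureFit) -> float:
    """Marginal log-likelihood at the posterior-mean point estimate."""
    return mixture_loglik(series_list, fit.curve(1), fit.curve(2), fit.w, fit.sigma_m)
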