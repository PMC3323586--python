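"""Shared MCMC machinery: adaptive random-walk blocks, split-chain R-hat,
and the posterior-draws container.

All model fits in this package run a blocked adaptive Metropolis-within-Gibbs
sampler: conditionally conjugate blocks (mixing weight, variances, population
mean, random-effects covariance) are drawn exactly, everything else moves by
Gaussian random walks whose step size is tuned to a target acceptance rate
during warmup (Robbins-Monro) and then frozen, so the retained chains are
valid MCMC.  Convergence is gated on the split-chain Gelman-Rubin diagnostic
(R-hat < 1.1) for every reported population-level scalar, which is why at
least two chains are always required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ValidationError

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1


@dataclass
class McmcConfig:
    """Chain layout.  Defaults favour quick, well-mixed runs of the blocked
    Gibbs samplers in this package; raise ``draws`` for publication use."""

    chains: int = 3
    warmup: int = 1000
    draws: int = 1000
    thin: int = 1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError(
                "need >= 2 chains for the split-chain Gelman-Rubin diagnostic"
            )
        for name in ("warmup", "draws", "thin"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


def split_rhat(x: np.ndarray) -> float:
    """Split-chain Gelman-Rubin diagnostic for one scalar.

    ``x`` has shape (chains, draws); each chain is split in half, so m = 2*chains
    sequences enter the between/within variance ratio.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("split_rhat expects an array of shape (chains >= 2, draws)")
    n = x.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0  # all sequences constant and equal
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


class AdaptiveRW:
    """Gaussian random-walk proposal with Robbins-Monro scale adaptation and
    (optionally) adaptive-Metropolis covariance learning.

    During warmup the log step size moves toward the target acceptance rate
    and, once enough states have been seen, proposals use the Cholesky factor
    of the running empirical covariance of the chain (Haario-style), which
    handles strongly correlated blocks.  After ``freeze()`` everything is
    fixed, so retained draws come from a valid Markov chain.
    """

    def __init__(self, dim: int, scale: float = 0.1, base=None, target: float = 0.28,
                 adapt_cov: bool = True, cov_start: int = 200):
        self.dim = dim
        self.log_s = math.log(scale)
        self.base = np.ones(dim) if base is None else np.asarray(base, dtype=float)
        self.target = target
        self.t = 0
        self.frozen = False
        self.adapt_cov = adapt_cov
        self.cov_start = cov_start
        self._n = 0
        self._mean = np.zeros(dim)
        self._m2 = np.zeros((dim, dim))
        self._chol: np.ndarray | None = None

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim)
        if self._chol is not None:
            step = self._chol @ z
        else:
            step = self.base * z
        return x + math.exp(self.log_s) * step

    def update_state(self, x: np.ndarray) -> None:
        """Feed the current chain state into the running covariance."""
        if self.frozen or not self.adapt_cov:
            return
        self._n += 1
        delta = x - self._mean
        self._mean += delta / self._n
        self._m2 += np.outer(delta, x - self._mean)
        if self._n >= max(self.cov_start, 2 * self.dim) and self._n % 50 == 0:
            cov = self._m2 / (self._n - 1)
            cov += 1e-8 * np.eye(self.dim) * max(np.trace(cov) / self.dim, 1e-8)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                return
            if self._chol is None:
                # switching preconditioner: restart the scale near 2.4/sqrt(d)
                self.log_s = math.log(2.4 / math.sqrt(self.dim))
            self._chol = chol

    def adapt(self, accepted: bool) -> None:
        if self.frozen:
            return
        self.t += 1
        gamma = self.t ** -0.6
        self.log_s += gamma * ((1.0 if accepted else 0.0) - self.target)
        self.log_s = min(max(self.log_s, -15.0), 5.0)

    def freeze(self) -> None:
        self.frozen = True


class VectorAdaptiveRW:
    """Independent adaptive random walks for n exchangeable units updated in
    parallel (e.g. per-individual parameter blocks).

    Each unit keeps its own scalar step size over a shared per-coordinate
    base scale and, once enough states have accumulated, its own empirical
    proposal covariance (batched Haario adaptation) — essential when some
    units have ridge-shaped conditionals, as near-linear trajectories do in
    the (alpha, tau) plane.
    """

    def __init__(self, n: int, dim: int, scale: float = 0.2, base=None,
                 target: float = 0.28, adapt_cov: bool = True, cov_start: int = 150):
        self.n, self.dim = n, dim
        self.log_s = np.full(n, math.log(scale))
        self.base = np.ones(dim) if base is None else np.asarray(base, dtype=float)
        self.target = target
        self.t = 0
        self.frozen = False
        self.adapt_cov = adapt_cov
        self.cov_start = cov_start
        self._k = 0
        self._mean = np.zeros((n, dim))
        self._m2 = np.zeros((n, dim, dim))
        self._chol: np.ndarray | None = None  # (n, dim, dim)

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((self.n, self.dim))
        if self._chol is not None:
            step = np.einsum("nij,nj->ni", self._chol, z)
        else:
            step = self.base[None, :] * z
        return x + np.exp(self.log_s)[:, None] * step

    def update_state(self, x: np.ndarray) -> None:
        if self.frozen or not self.adapt_cov:
            return
        self._k += 1
        delta = x - self._mean
        self._mean += delta / self._k
        self._m2 += np.einsum("ni,nj->nij", delta, x - self._mean)
        if self._k >= self.cov_start and self._k % 100 == 0:
            cov = self._m2 / (self._k - 1)
            jitter = 1e-6 * np.maximum(
                np.trace(cov, axis1=1, axis2=2) / self.dim, 1e-6
            )
            cov = cov + jitter[:, None, None] * np.eye(self.dim)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                return
            if self._chol is None:
                self.log_s[:] = math.log(2.4 / math.sqrt(self.dim))
            self._chol = chol

    def adapt(self, accepted: np.ndarray) -> None:
        if self.frozen:
            return
        self.t += 1
        gamma = self.t ** -0.6
        self.log_s += gamma * (accepted.astype(float) - self.target)
        np.clip(self.log_s, -15.0, 5.0, out=self.log_s)

    def freeze(self) -> None:
        self.frozen = True


def mh_accept(delta_logpost, rng: np.random.Generator):
    """Vector- or scalar-valued Metropolis-Hastings acceptance decision."""
    delta = np.asarray(delta_logpost, dtype=float)
    with np.errstate(over="ignore"):
        accept = np.log(rng.random(delta.shape if delta.ndim else None)) < delta
    return accept


def student_t_logpdf(x, df: float, loc: float = 0.0, scale: float = 2.5):
    """Non-standardized Student-t log density (df=1 gives the Cauchy that is
    the conventional weakly-informative default for regression coefficients)."""
    z = (np.asarray(x, dtype=float) - loc) / scale
    return (
        math.lgamma((df + 1) / 2)
        - math.lgamma(df / 2)
        - 0.5 * math.log(df * math.pi)
        - math.log(scale)
        - (df + 1) / 2 * np.log1p(z * z / df)
    )


def truncnorm_draw(mean: float, sd: float, lo: float, hi: float,
                   rng: np.random.Generator) -> float:
    """One draw from N(mean, sd²) truncated to (lo, hi), by inverse-CDF;
    degenerate far-tail intervals fall back to the nearest interior point."""
    from scipy.special import ndtr, ndtri

    a = ndtr((lo - mean) / sd) if np.isfinite(lo) else 0.0
    b = ndtr((hi - mean) / sd) if np.isfinite(hi) else 1.0
    if b - a < 1e-14:  # interval far in a tail; clamp just inside
        lo_f = lo if np.isfinite(lo) else hi - sd
        hi_f = hi if np.isfinite(hi) else lo + sd
        return float(np.clip(mean, lo_f + 1e-9 * sd, hi_f - 1e-9 * sd))
    u = rng.uniform(a, b)
    u = min(max(u, 1e-15), 1 - 1e-15)
    x = mean + sd * ndtri(u)
    return float(np.clip(x, lo, hi))


def truncated_invgamma_sd(ss: float, n: int, upper: float, rng: np.random.Generator) -> float:
    """Gibbs draw of a residual SD under a flat prior on the SD, truncated to
    (0, upper): sigma^2 | data ~ InvGamma((n-1)/2, ss/2)."""
    shape = max((n - 1) / 2.0, 0.5)
    for _ in range(1000):
        sig2 = (ss / 2.0) / rng.gamma(shape)
        if sig2 < upper * upper:
            return math.sqrt(sig2)
    return upper * 0.999  # pathological data; clamp at the prior bound


@dataclass
class PosteriorDraws:
    """MCMC output: one (chains, draws) array per scalar parameter, with
    convergence metadata and the model-comparison inputs attached."""

    params: dict[str, np.ndarray]
    warmup: int
    thin: int
    reported: list[str] = field(default_factory=list)  # scalars gated on R-hat
    rhat: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # loglik, K, n, model name, ...

    def __post_init__(self) -> None:
        if not self.params:
            raise ValidationError("empty posterior")
        if not self.reported:
            self.reported = list(self.params)
        if not self.rhat:
            self.rhat = {k: split_rhat(self.params[k]) for k in self.reported}

    @property
    def chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    @property
    def converged(self) -> bool:
        return all(np.isnan(r) or r < RHAT_THRESHOLD for r in self.rhat.values())

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.params[name].mean())

    def median(self, name: str) -> float:
        return float(np.median(self.params[name]))

    def interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        """Highest-posterior-density interval (the narrowest interval holding
        ``prob`` of the draws) — the convention for reporting skewed
        posteriors, and noticeably different from equal tails for the AFT
        coefficients and the Weibull shape."""
        x = np.sort(self.stacked(name))
        k = int(np.ceil(prob * x.size))
        widths = x[k - 1 :] - x[: x.size - k + 1]
        i = int(np.argmin(widths))
        return float(x[i]), float(x[i + k - 1])

    def eti(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval (quantiles)."""
        lo = (1 - prob) / 2
        x = self.stacked(name)
        return float(np.quantile(x, lo)), float(np.quantile(x, 1 - lo))

    def summary(self, names=None) -> pd.DataFrame:
        """Posterior medians and 2.5/97.5% quantiles, Table-style."""
        names = list(names) if names is not None else self.reported
        rows = []
        for name in names:
            x = self.stacked(name)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(x)),
                    "q2.5": float(np.quantile(x, 0.025)),
                    "q97.5": float(np.quantile(x, 0.975)),
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")
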