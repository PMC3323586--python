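"""Core domain types for dentin isotope series and their survival models.

Male Southern Elephant Seal teeth archive a lifelong record of foraging
location: each year deposits four dentin growth layers (two translucent,
synthesized ashore; two opaque, synthesized at sea), and the δ¹³C of every
layer proxies the latitude of the water mass the seal fed in.  The types here
carry that record from raw per-layer measurements through QC to the
per-individual trajectory parameters that act as survival covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class Context(str, Enum):
    """Where a growth layer was synthesized within the annual cycle."""

    ASHORE = "ashore"
    AT_SEA = "at_sea"


@dataclass(frozen=True)
class DentinRecord:
    """One sampled dentin growth layer.

    ``layer_index`` is 1-based and counts from the first-deposited
    (innermost, oldest) layer; ages are derived from it, never stored.
    """

    individual_id: str
    layer_index: int
    context: Context
    d13c: float  # ‰ vs VPDB
    cn_ratio: float  # C/N mass ratio, dimensionless

    def __post_init__(self) -> None:
        if self.layer_index < 1:
            raise ValidationError(
                f"layer_index must be >= 1, got {self.layer_index} "
                f"(individual {self.individual_id})"
            )
        if not self.cn_ratio > 0:
            raise ValidationError(
                f"cn_ratio must be positive, got {self.cn_ratio} "
                f"(individual {self.individual_id})"
            )
        if not isinstance(self.context, Context):
            object.__setattr__(self, "context", Context(self.context))


@dataclass
class IsotopeSeries:
    """One individual's age-indexed δ¹³C series plus its observed longevity.

    Ages sit on a quarter-year grid (one growth layer per quarter); the
    series cannot extend past death.
    """

    individual_id: str
    ages: np.ndarray  # years, strictly increasing
    values: np.ndarray  # ‰ VPDB
    longevity: float  # years
    qc_flags: np.ndarray | None = None  # per-point: passed the C/N filter

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape:
            raise ValidationError(
                f"ages and values differ in length for {self.individual_id}"
            )
        if self.ages.size and np.any(np.diff(self.ages) <= 0):
            raise ValidationError(f"ages not strictly increasing for {self.individual_id}")
        if not self.longevity > 0:
            raise ValidationError(f"longevity must be positive for {self.individual_id}")
        if self.ages.size and self.ages[-1] > self.longevity + 1e-9:
            raise ValidationError(
                f"series for {self.individual_id} extends past its longevity "
                f"({self.ages[-1]:.2f} > {self.longevity:.2f} yr)"
            )
        if self.qc_flags is None:
            self.qc_flags = np.ones(self.ages.size, dtype=bool)
        else:
            self.qc_flags = np.asarray(self.qc_flags, dtype=bool)

    def __len__(self) -> int:
        return self.ages.size


@dataclass(frozen=True)
class ChangePointParams:
    """The four broken-stick parameters summarizing one δ¹³C trajectory:
    value at the ontogenetic shift, age at the shift, and the slopes before
    and after it."""

    alpha: float  # ‰ VPDB at the change-point
    tau: float  # years
    beta1: float  # ‰/year before the shift
    beta2: float  # ‰/year after the shift

    def __post_init__(self) -> None:
        vals = (self.alpha, self.tau, self.beta1, self.beta2)
        if not all(np.isfinite(vals)):
            raise ValidationError(f"non-finite change-point parameters: {vals}")
        if not self.tau > 0:
            raise ValidationError(f"tau must be positive, got {self.tau}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.tau, self.beta1, self.beta2])


#: order of the trajectory parameters wherever they appear as a vector
PARAM_NAMES = ("alpha", "tau", "beta1", "beta2")


@dataclass
class PopulationParams:
    """The full generative truth of a cohort: random-effect mean and
    covariance of the trajectory parameters, residual measurement SD, AFT
    coefficients and Weibull shape.

    theta = (θ0, θ_alpha, θ_tau, θ_beta1, θ_beta2) forms the linear predictor
    η = θ0 + θ'b of the Weibull accelerated-failure-time model
    S(t) = exp(−e^η t^v); larger η means stochastically earlier death.
    """

    mu_re: np.ndarray  # (4,)
    sigma_re: np.ndarray  # (4, 4), symmetric PSD
    sigma_obs: float  # ‰ residual SD
    theta: np.ndarray  # (5,)
    shape: float  # Weibull shape v

    def __post_init__(self) -> None:
        self.mu_re = np.asarray(self.mu_re, dtype=float)
        self.sigma_re = np.asarray(self.sigma_re, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.mu_re.shape != (4,):
            raise ValidationError("mu_re must be a 4-vector")
        if self.sigma_re.shape != (4, 4):
            raise ValidationError("sigma_re must be 4x4")
        if not np.allclose(self.sigma_re, self.sigma_re.T, atol=1e-10):
            raise ValidationError("sigma_re must be symmetric")
        eigvals = np.linalg.eigvalsh(self.sigma_re)
        if eigvals.min() < -1e-10:
            raise ValidationError(
                f"sigma_re must be positive semi-definite (min eigenvalue {eigvals.min():.3g})"
            )
        if self.theta.shape != (5,):
            raise ValidationError("theta must be a 5-vector (intercept + 4 coefficients)")
        if not self.sigma_obs > 0:
            raise ValidationError("sigma_obs must be positive")
        if not self.shape > 0:
            raise ValidationError("Weibull shape must be positive")


@dataclass
class ModelScore:
    """One row of the AFT model-comparison table."""

    name: str
    K: int
    loglik: float
    aicc: float
    delta: float = np.nan
    weight: float = np.nan


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood pointwise 95% CI."""

    times: np.ndarray  # sorted unique event times
    survival: np.ndarray  # non-increasing, values just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
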