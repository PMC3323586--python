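# Methods

## The scientific problem

Male Southern Elephant Seals (*Mirounga leonina*) spend most of their life at
sea and are rarely re-sighted, so their longevity cannot realistically be
estimated by mark-recapture.  Teeth recovered from dead males offer a
work-around: dentin grows in increments (four layers per year — two deposited
ashore during breeding and moult, two at sea), remains metabolically inert
after deposition, and its δ¹³C tracks the latitudinal carbon-isotope gradient
of the Southern Ocean.  A tooth is therefore a life-long, quarter-year-
resolved archive of where its owner foraged, and counting layers gives the
age at death.  The question this package addresses is whether the *ontogeny
of foraging strategy* — in particular how stable the adult strategy is —
covaries with longevity.

## Models

### Broken-stick trajectory

Each individual's δ¹³C series is summarized by a change-point ("broken
stick") mean with four parameters b = (α, τ, β₁, β₂): the value at the
ontogenetic shift α (‰ VPDB), the age at the shift τ (yr), and linear slopes
before (β₁) and after (β₂) it (‰/yr).  The shift marks the transition from
maternal dependence (milk lipids are ¹³C-depleted, so β₁ > 0 as the signal
washes out) to an individual adult strategy; β₂ ≈ 0 is *foraging fidelity* —
a stable, unswitching strategy.  Observations are the mean plus i.i.d.
Gaussian noise σ_obs.  Across individuals, b is multivariate normal
(μ_re, Σ_re): a hierarchical random change-point model.

### Weibull accelerated failure time, fitted jointly

Longevity T follows a Weibull AFT with survival function

    S(t) = exp(−e^η t^v),    η = θ0 + θα α + θτ τ + θβ₁ β₁ + θβ₂ β₂.

A positive θ_j x_j accelerates death; v > 1 gives the monotonically
increasing (senescent) hazard expected here.  There is no censoring: every
tooth donor was found dead and aged.  Trajectory and survival are fitted as
a single posterior, so uncertainty in each individual's b propagates into θ.
The coefficient of scientific interest is θβ₂, the association between
foraging fidelity and longevity.

Three competitor AFT models differ only in the covariate construction:
*null* (η = θ0), *random* (the individual's mean-δ¹³C deviation from the
population mean), and *mixture* (a hard Subantarctic/Antarctic group label
from the growth mixture below).

Two variants of the joint model play distinct roles.  The **full** model
enters all four trajectory parameters in η; it is the model-comparison
entry and the input to variable selection, and at n ≈ 50 it is
over-parameterized — three of its four covariates fit noise, which inflates
the shape estimate and the magnitude of the surviving coefficient.  The
**final** model keeps only the post-shift slope (η = θ0 + θβ₂ β₂), the
specification SSVS supports, and is the better-calibrated choice for
reporting posterior summaries; the recovery demonstrations in the test
suite and `scripts/acceptance.py` use it.  Both are the same
`fit_joint` with a different `covariates` argument.

### Model comparison

Models are compared by AICc (−2logL + 2K + 2K(K+1)/(n−K−1)) and Akaike
weights.  The log-likelihood scored is the Weibull survival likelihood at
posterior means, and K counts the AFT parameters only (null 2; random and
mixture 3; joint 6).  The longitudinal submodels serve to *construct* the
survival covariates; scoring their likelihoods would compare models on
different data and let hundreds of isotope points swamp fifty death times.
K-counting is configurable by passing custom scores, but the packaged
comparison is internally consistent by construction.

### Growth mixture

A descriptive two-component mixture of δ¹³C versus integer-year age class:
each individual belongs for life to component 1 (Subantarctic, isotopically
heavier) or component 2 (Antarctic, lighter), with mixing proportion w and
per-class mean curves mu1, mu2 sharing one residual SD.  Identification
constraints: mu2(t) < mu1(t) at every class (removes label switching), mu1
non-decreasing, mu2 non-increasing (monotone equilibration toward the
habitat signature).  Both hold in 100% of retained draws because each curve
value is drawn from its exact full conditional truncated to the allowed
interval — no rejection step, no post-hoc filtering.

## Sampling

All fits use a blocked adaptive Metropolis-within-Gibbs sampler written for
this package:

* per-individual b_i blocks move by vectorized random walks — one joint
  4-dimensional proposal with a per-individual empirical covariance learned
  during warmup (batched Haario adaptation; essential because near-linear
  trajectories make the (α, τ) conditional a narrow ridge), plus a
  coordinate-wise pass with per-(individual, coordinate) step sizes, plus an
  independence proposal for τ from its conditional prior (the only move that
  can hop between the local modes a broken-stick profile likelihood can
  have);
* μ_re is a conjugate normal draw; Σ_re a conjugate inverse-Wishart draw;
  σ_obs and the mixture residual SD are truncated inverse-gamma draws under
  flat priors on the SD;
* (θ, log v) moves as one adaptive-Metropolis block on internally centered
  and standardized covariates (θ is reported on the raw scale), which
  removes the intercept/covariate collinearity that cripples naive random
  walks;
* all adaptation freezes at the end of warmup, so retained draws form a
  valid Markov chain.

Convergence is gated on split-chain Gelman-Rubin R-hat < 1.1 for every
reported population-level scalar (hence ≥ 2 chains, initialized
overdispersed around per-individual least-squares broken-stick fits).  A
fit that misses the gate is returned flagged, not discarded.

Stochastic search variable selection (SSVS) over the four AFT covariates
uses a continuous spike-and-slab prior (spike SD 0.025, slab SD 2.5 on
standardized covariates, Bernoulli(0.5) inclusion).  Spike↔slab moves are
joint (γ_j, θ_j) proposals with the θ_j redrawn from a pilot-posterior
approximation, avoiding the sticking of within-state-only samplers.  A
zero-width spike degenerates to all covariates always included.

## Priors

* θ: Student-t(df 7, scale 2.5) centered at 0 (scale 10 for the intercept).
  The family's df 1 (Cauchy) limit is the textbook weakly-informative
  default; df 7 keeps the heavy tails but adds mild shrinkage, which is
  better calibrated for cohorts of ~50.
* v: Uniform(0, 10) — spans decreasing through strongly senescent hazards.
* σ_obs, mixture residual SD: Uniform(0, 10) ‰ on the SD.
* Σ_re: inverse-Wishart, df p+2 = 6 (the weakest with a finite mean), scale
  diag(1, 1, 0.25, 0.25) — chosen for conjugacy with the Gibbs blocks; with
  n = 50 individuals the data dominate it.  The recovery and coverage
  behaviour of the package is insensitive to replacing it with other
  weakly-informative covariance priors, which is the property that matters.
* μ_re: Normal, center (−20, 3, 0, 0), SDs (10, 3, 3, 3).
* Mixture: w ~ Beta(2, 2); curve values Normal(−20, 10²) truncated by the
  constraints.

## Synthetic cohorts

No tooth collection of this kind is publicly deposited, so the package
ships a generator that produces cohorts with exactly the structure the
joint model assumes, plus the two nuisances the QC stage must handle.

Default scenario (every value overridable):

| quantity | default | meaning |
|---|---|---|
| μ_re | (−21 ‰, 2.5 yr, 0.6, −0.3 ‰/yr) | population mean trajectory |
| SDs of b | (1.5 ‰, 0.5 yr, 0.2, 0.5 ‰/yr) | between-individual spread |
| corr(τ, β₂) | −0.4 | early shifters settle into stabler strategies |
| σ_obs | 0.4 ‰ | layer-level measurement + micro-environment noise |
| θ | (−6.5, 0, 0, 0, −1.5) | only the post-shift slope drives survival |
| v | 3 | senescent hazard; median longevity ≈ 7 yr |
| layers/yr | 4 (2 ashore + 2 at sea) | quarter-year age grid |
| diagenetic fraction | 5% | C/N pushed outside the collagen range (2.9–3.6) |

The trajectory means and θ follow the qualitative biology (positive
pre-shift slope from weaning, near-zero mean adult slope, increasing
hazard, fidelity associated with longer life).  The between-individual SDs
and the τ–β₂ correlation are not dictated anywhere; they were fixed once,
before any estimation runs, from two considerations: (i) plausibility — a
±2 SD range of adult slopes spans a faithful forager (β₂ ≈ 0) to a seal
drifting ≈ 1.3 ‰/yr across water masses, and α spans the ≈ 5 ‰ Subantarctic–
Antarctic contrast; (ii) a closed-form Weibull-regression power analysis:
the information about θβ₂ in n individuals is (|θβ₂|·sd(β₂)·√n / 1.283)²,
so sd(β₂) = 0.5 puts the effect at z ≈ 4 at n = 50 — detectable but not
trivial, the regime in which AICc selection between the joint and null
models is actually informative.  Death times are drawn by inverting S(t);
individuals dying inside their first year are redrawn (a beach-cast tooth
that thin would not be aged and sampled), and the last incomplete quarter
deposits no layer, so a series never outlives its owner.

What the generator does **not** emulate: the 1–4 month isotopic
equilibration lag of dentin after a diet change (commensurate with haul-out
durations, hence ignored); ageing error from miscounted layers (available
as an optional perturbation, never propagated into the likelihood);
strategy switching beyond a single change-point; any systematic
ashore/at-sea δ¹³C offset (the default is none, and the QC stage's per-seal
Kolmogorov-Smirnov comparison is there to detect one).  Passing recovery
tests on these cohorts therefore demonstrates that the estimation machinery
is correct under its own assumptions — not that those assumptions hold for
any particular real population.

## Numerical choices and edge cases

* Ages: layer k ↦ k/4 yr (end-of-layer convention); discarded diagenetic
  layers leave gaps rather than re-indexing ages; the models accept
  irregular grids.
* At age exactly τ the "after" branch applies (right-continuous); the mean
  is continuous there regardless.
* τ is truncated positive in the generator by redrawing the offending draw
  only (keeps cohort size exact; bias is negligible at τ = 2.5 ± 0.5).
  The fitter leaves τ unconstrained — the hierarchy keeps it in range.
* AICc requires n > K + 1 and is refused otherwise; Akaike weights are
  computed after subtracting the minimum AICc, making them shift-invariant
  by construction.
* Kaplan-Meier uses the product-limit estimator (lifelines) with
  Greenwood-type intervals; without censoring it equals 1 − ECDF exactly,
  which the tests assert.  The Weibull probability plot drops the final
  point (S = 0) and needs ≥ 3 usable points.
* The empirical hazard counts deaths in left-open bins (a, b] over
  person-time at risk; a bin with no person-time is reported missing, not
  zero.  The smoother is lowess, span 0.75.
* Credible intervals are reported as highest-posterior-density (HPD)
  intervals — the narrowest interval holding 95% of the draws — which
  matters for the right-skewed shape and left-skewed coefficient
  posteriors; equal-tailed quantiles are also exposed (`eti`) and appear in
  the summary tables.
* Posterior CSVs are written at %.17g and read with round-trip float
  parsing, so read(write(x)) is bit-identical; a posterior containing NaN
  is refused (it signals a failed sampler).
* Pipeline determinism: one `SeedSequence` per run is spawned into
  per-stage children; summaries are dumped with sorted keys, so a repeated
  run is byte-identical.

## Problem sizes

The packaged defaults (replicate counts of 10–20 cohorts of n = 50, chains
2 × 1000 after 1000 warmup) are sized so a complete replicate — simulate,
fit, diagnose — takes seconds on one core, which makes the frequentist
acceptance checks (coverage counts, selection frequencies) cheap to rerun
end to end.  Production analyses of a real collection should raise chains
to 3 and draws to ≥ 5000; every knob is in `RunConfig`.

## Known limitations

* AICc with hierarchical random effects has no canonical K; the package's
  convention (AFT parameters only) is one defensible choice, stated openly.
* Small cohorts inflate AFT coefficient magnitudes (a known property of
  Weibull regression MLEs that the mild t₇ shrinkage only partly offsets);
  credible intervals remain approximately calibrated, point medians less so.
* The mixture model assumes a common curve shape within a component and
  exactly two components; it is a descriptive summary, not the inferential
  centrepiece.
* No censoring support: inapplicable to live-capture designs.
* Left-truncation induced by "only seals surviving their first year leave a
  usable tooth" is mirrored in the generator but deliberately not modelled
  in the likelihood; at the default hazard it affects ≈ 0.2% of draws.
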