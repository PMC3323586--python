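# dentinsurv

Joint change-point/survival modelling of dentin δ¹³C life-history archives.

Male Southern Elephant Seals spend most of their lives at sea, which makes
their longevity nearly impossible to measure by mark-recapture.  Teeth from
beach-cast males side-step that: dentin deposits four growth layers a year
(two ashore, two at sea), is inert after deposition, and its δ¹³C proxies
the foraging latitude in the Southern Ocean — so one tooth is both an age
at death and a quarter-year-resolved foraging biography.  `dentinsurv`
implements the statistical machinery for asking whether foraging strategy
predicts life-span from such archives:

* a **hierarchical broken-stick model** of each δ¹³C series — four
  parameters per seal: value at the ontogenetic shift α, age at the shift
  τ, slope before (β₁) and after (β₂) it — fitted **jointly** with a
  **Weibull accelerated-failure-time model**,
  S(t) = exp(−e^η t^v), η = θ0 + θα·α + θτ·τ + θβ₁·β₁ + θβ₂·β₂,
  so change-point uncertainty propagates into the survival coefficients.
  θβ₂ measures the association between *foraging fidelity* (a flat adult
  slope) and longevity;
* three competitor AFT models (intercept-only null; individual mean-δ¹³C
  deviation; binary foraging-group membership) compared by **AICc** and
  Akaike weights;
* a constrained **two-component growth mixture** (Subantarctic above
  Antarctic at every age, monotone curves — label switching is impossible
  by construction);
* QC replicating dentin practice: C/N collagen-range screening for
  diagenesis (default 2.9–3.6), per-seal ashore/at-sea Kolmogorov-Smirnov
  comparison;
* diagnostics: Kaplan-Meier with Greenwood bands, binned empirical hazard
  with a lowess smooth, Weibull probability plot, posterior-predictive KS
  goodness-of-fit, predictor correlations, and spike-and-slab variable
  selection (SSVS);
* a **synthetic-cohort generator** with exactly the generative structure
  the joint model assumes, because no dataset of this kind is publicly
  deposited — every claim the test suite makes is checked against known
  ground truth.

All Bayesian fits run on a fast, package-internal blocked adaptive
Metropolis-within-Gibbs sampler with split-chain R-hat convergence gating
(see `docs/methods.md`).

## Worked example

```python
from dentinsurv.io_config import RunConfig, run_pipeline

cfg = RunConfig(seed=11, n_individuals=40,
                mcmc={"chains": 2, "warmup": 500, "draws": 500})
summary = run_pipeline(cfg, "simulate", outdir="run")
for row in summary["comparison"]:
    print(f"{row['model']:8s} K={row['K']} logL={row['loglik']:7.2f} "
          f"AICc={row['AICc']:7.2f} w={row['weight']:.3f}")
```

prints (machine-exact values will vary with BLAS, not with the seed):

```
joint    K=6 logL= -87.13 AICc= 188.81 w=0.998
random   K=3 logL= -97.61 AICc= 201.89 w=0.001
null     K=2 logL=-101.68 AICc= 207.68 w=0.000
mixture  K=3 logL=-100.64 AICc= 207.95 w=0.000
```

The simulated cohort was generated with the post-shift slope driving
survival (θβ₂ = −1.5), and the joint change-point/survival model carries
essentially all the Akaike weight — the model-selection signature of a real
fidelity-longevity association.  The same run writes `summary.json`
(posterior medians and 95% intervals for θ, v, σ_obs, the population mean
and covariance; the QC report; SSVS inclusion probabilities — here β₂ at
1.00 against 0.09–0.11 for α and τ), the per-stage CSV artefacts, and the
figures.  Re-running with the same seed reproduces `summary.json` byte for
byte.

The same stages are available from a shell:

```sh
dentinsurv --seed 11 --outdir run run-all
dentinsurv --seed 1 simulate
dentinsurv prep --records run/records.csv --longevity run/longevity.csv
dentinsurv fit-survival --series run/series.csv --model joint
```

## Layout

```
src/dentinsurv/
  types.py       # DentinRecord, IsotopeSeries, ChangePointParams, ...
  synthetic.py   # cohort generator (trajectories, deaths, dentin records)
  prep.py        # layer->age mapping, C/N filter, series assembly, KS QC
  mixture.py     # constrained two-component growth mixture
  joint.py       # joint change-point/Weibull AFT + the three competitors
  diagnostics.py # AICc/weights, KM, hazard, Weibull plot, KS GOF, SSVS
  mcmc.py        # adaptive MH/Gibbs blocks, split R-hat, draws container
  io_config.py   # CSV I/O, YAML config, pipeline driver
  cli.py         # `dentinsurv` command group
```
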