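"""CSV readers/writers, run configuration and the pipeline driver.

The interchange formats are deliberately minimal: comma-separated UTF-8 with
a required header and "." decimals.  A full analysis run — simulate (or
read) → QC prep → growth mixture → four survival models → AICc comparison →
diagnostics — is orchestrated by :func:`run_pipeline` and is a pure function
of (config.seed, input): re-running writes byte-identical JSON summaries.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, joint, mixture, prep, synthetic
from .mcmc import McmcConfig, PosteriorDraws
from .types import Context, DentinRecord, IsotopeSeries, PARAM_NAMES, ValidationError

logger = logging.getLogger(__name__)

DENTIN_FIELDS = ["individual_id", "layer_index", "context", "d13c", "cn_ratio"]


class FormatError(ValueError):
    """File does not conform to the expected CSV layout."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# ------------------------------------------------------------------ CSV I/O


def read_dentin_csv(path) -> list[DentinRecord]:
    """Read per-layer dentin records; malformed numeric cells are reported
    with their row numbers (header = row 1)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header required")
        missing = [c for c in DENTIN_FIELDS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        records, bad_rows = [], []
        for rownum, row in enumerate(reader, start=2):
            try:
                rec = DentinRecord(
                    individual_id=row["individual_id"],
                    layer_index=int(row["layer_index"]),
                    context=Context(row["context"]),
                    d13c=float(row["d13c"]),
                    cn_ratio=float(row["cn_ratio"]),
                )
            except (TypeError, KeyError, ValueError) as exc:  # includes ValidationError
                bad_rows.append((rownum, str(exc)))
                continue
            records.append(rec)
    if bad_rows:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in bad_rows[:10])
        raise ValidationError(f"{path}: {len(bad_rows)} invalid row(s): {detail}")
    return records


def write_dentin_csv(records: list[DentinRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DENTIN_FIELDS)
        for r in records:
            writer.writerow(
                [r.individual_id, r.layer_index, r.context.value, repr(r.d13c),
                 repr(r.cn_ratio)]
            )


def read_longevity_csv(path) -> dict[str, float]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("individual_id", "longevity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    return dict(zip(df["individual_id"].astype(str), df["longevity"].astype(float)))


def write_longevity_csv(longevity_by_id: dict[str, float], path) -> None:
    pd.DataFrame(
        {"individual_id": list(longevity_by_id), "longevity": list(longevity_by_id.values())}
    ).to_csv(path, index=False, float_format='%.17g')


def write_series_csv(series_list: list[IsotopeSeries], path) -> None:
    rows = []
    for s in series_list:
        for age, val, qc in zip(s.ages, s.values, s.qc_flags):
            rows.append({"individual_id": s.individual_id, "age": age, "d13c": val,
                         "longevity": s.longevity, "qc_pass": bool(qc)})
    pd.DataFrame(rows).to_csv(path, index=False, float_format='%.17g')


def read_series_csv(path) -> list[IsotopeSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for sid, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("age")
        out.append(
            IsotopeSeries(
                individual_id=str(sid),
                ages=grp["age"].to_numpy(),
                values=grp["d13c"].to_numpy(),
                longevity=float(grp["longevity"].iloc[0]),
                qc_flags=grp["qc_pass"].to_numpy() if "qc_pass" in grp else None,
            )
        )
    return out


def write_posterior_csv(draws: PosteriorDraws, path) -> None:
    """One row per retained draw with chain and iteration columns; floats are
    written at full (round-trip) precision, so read-back is bit-identical."""
    names = list(draws.params)
    if not names:
        raise ValidationError("empty posterior")
    mats = [np.asarray(draws.params[k], dtype=float) for k in names]
    if any(not np.all(np.isfinite(m)) for m in mats):
        raise ValidationError("posterior contains NaN/inf — the sampler failed")
    n_chains, n_draws = mats[0].shape
    cols = {"chain": np.repeat(np.arange(n_chains), n_draws),
            "iteration": np.tile(np.arange(n_draws), n_chains)}
    for k, m in zip(names, mats):
        cols[k] = m.reshape(-1)
    pd.DataFrame(cols).to_csv(path, index=False, float_format='%.17g')


def read_posterior_csv(path) -> PosteriorDraws:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("chain", "iteration"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    df = df.sort_values(["chain", "iteration"])
    chains = df["chain"].nunique()
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    params = {k: df[k].to_numpy().reshape(chains, -1) for k in names}
    return PosteriorDraws(params=params, warmup=0, thin=1)


# ------------------------------------------------------------- configuration


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the input data."""

    seed: int = 0
    n_individuals: int = 50
    quarters_per_year: int = 4
    cn_bounds: tuple[float, float] = prep.DEFAULT_CN_BOUNDS
    frac_bad: float = 0.05
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(chains=2, warmup=500, draws=500))
    priors: dict = field(default_factory=dict)  # scalar overrides for JointPriors
    run_ssvs: bool = True
    figures: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.mcmc, dict):
            self.mcmc = McmcConfig(**self.mcmc)
        self.cn_bounds = tuple(float(x) for x in self.cn_bounds)
        if len(self.cn_bounds) != 2 or not self.cn_bounds[0] < self.cn_bounds[1]:
            raise ValidationError("cn_bounds must be (low, high) with low < high")
        if self.quarters_per_year < 1:
            raise ValidationError("quarters_per_year must be >= 1")
        if self.n_individuals < 2:
            raise ValidationError("n_individuals must be >= 2")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        known = set(vars(joint.JointPriors()))
        unknown = set(self.priors) - known
        if unknown:
            raise ValidationError(f"unknown prior hyperparameter(s): {sorted(unknown)}")

    def joint_priors(self) -> joint.JointPriors:
        return joint.JointPriors(**self.priors)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML run configuration (or defaults), validating every field."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a YAML mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)


# ------------------------------------------------------------------ pipeline


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, input_path="simulate", outdir="run") -> dict:
    """Execute the full analysis and write all artefacts under ``outdir``.

    ``input_path`` is either the string ``"simulate"`` (generate a synthetic
    cohort from the default population truth) or a directory containing
    ``records.csv`` and ``longevity.csv``.  Returns the summary dict, which
    is also written as ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    summary: dict = {"seed": config.seed}

    def stage(name):
        logger.info("stage %s: seed=%d", name, config.seed)

    # ---- stage 1: input -----------------------------------------------------
    try:
        stage("input")
        if input_path == "simulate":
            cohort = synthetic.simulate_cohort(
                config.n_individuals,
                quarters_per_year=config.quarters_per_year,
                frac_bad=config.frac_bad,
                cn_good_range=config.cn_bounds,
                seed=seeds[0],
            )
            records = cohort.records
            longevity_by_id = {s.individual_id: s.longevity for s in cohort.series}
            write_dentin_csv(records, outdir / "records.csv")
            write_longevity_csv(longevity_by_id, outdir / "longevity.csv")
            truth = {
                "mu_re": cohort.population.mu_re, "sigma_re": cohort.population.sigma_re,
                "sigma_obs": cohort.population.sigma_obs, "theta": cohort.population.theta,
                "shape": cohort.population.shape,
                "individual_params": [p.as_array() for p in cohort.individual_params],
            }
            (outdir / "truth.json").write_text(
                json.dumps(_jsonify(truth), sort_keys=True, indent=1))
        else:
            records = read_dentin_csv(Path(input_path) / "records.csv")
            longevity_by_id = read_longevity_csv(Path(input_path) / "longevity.csv")
        summary["input"] = {
            "n_records": len(records), "n_individuals": len(longevity_by_id),
            "records_digest": _digest(outdir / "records.csv")
            if input_path == "simulate" else _digest(Path(input_path) / "records.csv"),
        }
    except Exception as exc:
        raise PipelineError(f"stage 'input' failed: {exc}") from exc

    # ---- stage 2: prep ------------------------------------------------------
    try:
        stage("prep")
        kept, discard = prep.filter_cn(records, *config.cn_bounds)
        series = prep.assemble_series(kept, longevity_by_id, config.quarters_per_year)
        _, n_signif = prep.ashore_vs_atsea_cohort(records)
        write_series_csv(series, outdir / "series.csv")
        summary["prep"] = {
            "discarded_layers": discard.total,
            "kept_layers": len(kept),
            "ashore_vs_atsea_significant": n_signif,
        }
    except Exception as exc:
        raise PipelineError(f"stage 'prep' failed: {exc}") from exc

    # ---- stage 3: growth mixture -------------------------------------------
    try:
        stage("fit-mixture")
        mix = mixture.fit_growth_mixture(series, mcmc=config.mcmc,
                                         seed=int(seeds[1].generate_state(1)[0] % 2**31))
        pd.DataFrame({"individual_id": mix.individual_ids,
                      "p_component1": mix.class_prob}).to_csv(
            outdir / "class_prob.csv", index=False)
        write_posterior_csv(mix.draws, outdir / "posterior_mixture_curves.csv")
        summary["mixture"] = {
            "w_mean": mix.w, "sigma_m_mean": mix.sigma_m,
            "n_component1": int((mix.hard_assignment() == 1).sum()),
            "converged": mix.converged,
            "marginal_loglik": mixture.mixture_loglik_from_fit(series, mix),
        }
    except Exception as exc:
        raise PipelineError(f"stage 'fit-mixture' failed: {exc}") from exc

    # ---- stage 4: survival models ------------------------------------------
    try:
        stage("fit-survival")
        priors = config.joint_priors()
        longevs = np.array([s.longevity for s in series])
        fits = {}
        fits["joint"] = joint.fit_joint(series, priors, config.mcmc,
                                        seed=int(seeds[2].generate_state(1)[0] % 2**31))
        fits["null"] = joint.fit_null(longevs, priors, config.mcmc,
                                      seed=int(seeds[3].generate_state(1)[0] % 2**31))
        fits["random"] = joint.fit_random(series, priors, config.mcmc,
                                          seed=int(seeds[4].generate_state(1)[0] % 2**31))
        groups = (mix.hard_assignment() == 2).astype(int)
        if np.unique(groups).size < 2:  # degenerate single-strategy cohort
            logger.warning("single foraging group; mixture AFT skipped")
            fits["mixture"] = None
        else:
            fits["mixture"] = joint.fit_mixture_aft(
                longevs, groups, priors, config.mcmc,
                seed=int(seeds[5].generate_state(1)[0] % 2**31))
        for name, f in fits.items():
            if f is None:
                continue
            write_posterior_csv(
                PosteriorDraws(params={k: f.params[k] for k in f.reported},
                               warmup=f.warmup, thin=f.thin),
                outdir / f"posterior_{name}.csv")
        jsum = fits["joint"].summary()
        summary["survival"] = {
            "joint": {p: {"median": fits["joint"].median(p),
                          "hpd_lower": fits["joint"].interval(p)[0],
                          "hpd_upper": fits["joint"].interval(p)[1],
                          "rhat": fits["joint"].rhat[p]}
                      for p in jsum.index},
            "converged": {k: bool(f.converged) for k, f in fits.items() if f is not None},
        }
    except Exception as exc:
        raise PipelineError(f"stage 'fit-survival' failed: {exc}") from exc

    # ---- stage 5: comparison ------------------------------------------------
    try:
        stage("compare")
        table = diagnostics.score_models([f for f in fits.values() if f is not None])
        table.to_csv(outdir / "model_comparison.csv", index=False)
        summary["comparison"] = table.to_dict(orient="records")
    except Exception as exc:
        raise PipelineError(f"stage 'compare' failed: {exc}") from exc

    # ---- stage 6: diagnostics ----------------------------------------------
    try:
        stage("diagnose")
        km = diagnostics.kaplan_meier(longevs)
        wp = diagnostics.weibull_probability_plot(longevs)
        pred = diagnostics.posterior_predictive_longevities(
            fits["joint"], n_per_draw=2,
            seed=int(seeds[5].generate_state(2)[1] % 2**31))
        d_gof, p_gof = diagnostics.ks_gof(longevs, pred)
        b_mean = fits["joint"].extra["b_mean"]
        corr = diagnostics.predictor_correlations(b_mean)
        summary["diagnostics"] = {
            "km_final_survival": float(km.survival[-1]),
            "weibull_plot": {"slope": wp.slope, "r2": wp.r2},
            "ks_gof": {"D": d_gof, "p": p_gof},
            "predictor_correlations": {
                f"{a}:{b}": float(corr[i, j])
                for i, a in enumerate(PARAM_NAMES)
                for j, b in enumerate(PARAM_NAMES) if i < j},
        }
        if config.run_ssvs:
            incl, _ = diagnostics.ssvs(
                b_mean, longevs, priors, config.mcmc,
                seed=int(seeds[4].generate_state(2)[1] % 2**31))
            summary["diagnostics"]["ssvs_inclusion"] = {
                p: float(incl[i]) for i, p in enumerate(PARAM_NAMES)}
        if config.figures:
            from . import plots
            plots.plot_profiles(series, mix, outdir / "fig_profiles.png")
            plots.plot_survival(longevs, fits["joint"], outdir / "fig_survival.png")
            plots.plot_weibull(wp, outdir / "fig_weibull.png")
    except Exception as exc:
        raise PipelineError(f"stage 'diagnose' failed: {exc}") from exc

    payload = json.dumps(_jsonify(summary), sort_keys=True, indent=1)
    (outdir / "summary.json").write_text(payload)
    logger.info("pipeline complete; summary digest %s",
                hashlib.sha256(payload.encode()).hexdigest()[:16])
    return summary
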