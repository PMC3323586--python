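"""Raw dentin records → QC-filtered, age-indexed isotope series.

Each tooth deposits four growth layers per year (two ashore, two at sea),
so layer k is stamped with age k/4 (end-of-layer convention).  Layers whose
C/N mass ratio falls outside the collagen range are treated as
diagenetically altered and discarded; discarded layers leave gaps in the age
grid rather than re-indexing ages (the models tolerate irregular grids).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import Context, DentinRecord, IsotopeSeries, ValidationError

logger = logging.getLogger(__name__)

#: standard collagen C/N mass-ratio acceptance range used to screen diagenesis
DEFAULT_CN_BOUNDS = (2.9, 3.6)


def layer_age_map(layer_index: int, quarters_per_year: int = 4) -> float:
    """Age (years) at the end of growth layer ``layer_index`` (1-based)."""
    if layer_index < 1:
        raise ValidationError(f"layer_index must be >= 1, got {layer_index}")
    return layer_index / quarters_per_year


@dataclass
class DiscardReport:
    """Per-individual and total counts of C/N-rejected layers."""

    per_individual: dict[str, int] = field(default_factory=dict)
    total: int = 0


def filter_cn(
    records: list[DentinRecord], low: float = DEFAULT_CN_BOUNDS[0], high: float = DEFAULT_CN_BOUNDS[1]
) -> tuple[list[DentinRecord], DiscardReport]:
    """Keep records with low <= C/N <= high; report what was discarded."""
    if not low < high:
        raise ValidationError("C/N bounds must satisfy low < high")
    kept = []
    discards: Counter = Counter()
    for r in records:
        if low <= r.cn_ratio <= high:
            kept.append(r)
        else:
            discards[r.individual_id] += 1
    report = DiscardReport(per_individual=dict(discards), total=sum(discards.values()))
    if report.total:
        logger.info("C/N filter discarded %d of %d layers", report.total, len(records))
    return kept, report


def assemble_series(
    records: list[DentinRecord],
    longevity_by_id: dict[str, float],
    quarters_per_year: int = 4,
) -> list[IsotopeSeries]:
    """Group records per individual into an age-sorted isotope series.

    Individuals appear in order of first occurrence.  Duplicate
    (id, layer_index) pairs and ids lacking a longevity entry are errors.
    """
    by_id: dict[str, dict[int, DentinRecord]] = defaultdict(dict)
    order: list[str] = []
    for r in records:
        if r.individual_id not in by_id:
            order.append(r.individual_id)
        if r.layer_index in by_id[r.individual_id]:
            raise ValidationError(
                f"duplicate layer {r.layer_index} for individual {r.individual_id}"
            )
        by_id[r.individual_id][r.layer_index] = r
    out = []
    for sid in order:
        if sid not in longevity_by_id:
            raise ValidationError(f"no longevity entry for individual {sid}")
        layers = sorted(by_id[sid])
        ages = np.array([layer_age_map(k, quarters_per_year) for k in layers])
        values = np.array([by_id[sid][k].d13c for k in layers])
        out.append(
            IsotopeSeries(
                individual_id=sid,
                ages=ages,
                values=values,
                longevity=float(longevity_by_id[sid]),
            )
        )
    return out


def ashore_vs_atsea_test(records: list[DentinRecord]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of δ¹³C measured in layers
    synthesized ashore versus at sea, for one individual.

    Layers grown ashore are kept in all downstream analyses; this test checks
    whether fasting physiology leaves a detectable isotopic imprint.
    """
    ashore = [r.d13c for r in records if r.context == Context.ASHORE]
    at_sea = [r.d13c for r in records if r.context == Context.AT_SEA]
    if len(ashore) < 2 or len(at_sea) < 2:
        raise ValidationError("need >= 2 values in each context group")
    res = stats.ks_2samp(ashore, at_sea, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ashore_vs_atsea_cohort(
    records: list[DentinRecord], alpha: float = 0.05
) -> tuple[dict[str, tuple[float, float]], int]:
    """Run the ashore/at-sea KS test per individual across a cohort.

    Returns per-individual (D, p) and the count of individuals significant at
    ``alpha``.  Individuals with a context group of fewer than two values are
    skipped with a warning.
    """
    by_id: dict[str, list[DentinRecord]] = defaultdict(list)
    for r in records:
        by_id[r.individual_id].append(r)
    results: dict[str, tuple[float, float]] = {}
    n_signif = 0
    for sid, recs in by_id.items():
        try:
            d, p = ashore_vs_atsea_test(recs)
        except ValidationError:
            logger.warning("skipping %s: a context group has < 2 values", sid)
            continue
        results[sid] = (d, p)
        if p < alpha:
            n_signif += 1
    return results, n_signif
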