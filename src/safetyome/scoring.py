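"""Per-target evidence scores.

Each target's evidence breadth is condensed into a single number in four
steps:

1. raw score       = (sum of per-source record counts) * ln(n_unique_sources + 1)
2. Z-normalization = (raw - mean) / population std over the cohort
3. log transform   = ln(Z - min(Z) + 1), damping heavy right tails
4. min-max rescale to [0, 10]

The unique-source multiplier rewards targets seen independently in several
databases while preventing a single prolific database from dominating; the
log step keeps a handful of extremely well-studied genes from compressing
everyone else onto the bottom of the scale.

Percentile ranks (0-100) of the scaled score drive the downstream
safetyome cutoff; ties share the rank of the lowest member.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["gene_symbol", "raw", "z", "logz", "scaled", "percentile"]


@dataclass
class EvidenceProfile:
    """Per-source deduplicated association counts for one gene."""

    gene_symbol: str
    counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_unique_sources(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


def raw_score(profile: EvidenceProfile) -> float:
    """Evidence-breadth raw score: total records times ln(unique sources + 1)."""
    for src, c in profile.counts.items():
        if c < 0:
            raise ValidationError(
                f"negative count {c} for source {src!r} on gene {profile.gene_symbol!r}"
            )
    total = sum(profile.counts.values())
    return float(total) * math.log(profile.n_unique_sources + 1)


def profiles_from_records(records: pd.DataFrame) -> list[EvidenceProfile]:
    """Build per-gene evidence profiles from a harmonized association table.

    Counts are the number of deduplicated (gene, trait, source) records each
    source contributes, so a database listing one gene under many distinct
    traits counts each trait once.
    """
    counts = (
        records.groupby(["gene_symbol", "source_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    return [
        EvidenceProfile(gene, {s: int(c) for s, c in row.items() if c > 0})
        for gene, row in counts.iterrows()
    ]


def percentile_rank(values: Iterable[float]) -> np.ndarray:
    """Percentile ranks in [0, 100): 100 * (# strictly below) / N, ties shared."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("percentile_rank requires at least one value")
    strictly_below = rankdata(arr, method="min") - 1
    return 100.0 * strictly_below / arr.size


def scale_scores(raws: Iterable[tuple[str, float]]) -> pd.DataFrame:
    """Chain Z-normalization, log transform and 0-10 min-max rescaling.

    Returns a frame with columns gene_symbol, raw, z, logz, scaled,
    percentile. Degenerate cohorts (a single target, or all raw scores
    equal) cannot be rescaled; every target is then assigned scaled = 10 and
    percentile = 0 with a logged warning, so that any percentile cutoff
    retains the whole cohort instead of silently zeroing uniform evidence.
    """
    items = list(raws)
    if not items:
        raise ValidationError("scale_scores requires a non-empty cohort")
    genes = [g for g, _ in items]
    raw = np.asarray([r for _, r in items], dtype=float)

    sigma = raw.std()  # population std: the cohort is the whole population
    if sigma == 0:
        logger.warning(
            "degenerate cohort (%d targets, all raw scores equal): "
            "assigning scaled score 10 to every target",
            len(items),
        )
        z = np.zeros_like(raw)
        logz = np.zeros_like(raw)
        scaled = np.full_like(raw, 10.0)
        pct = np.zeros_like(raw)
    else:
        z = (raw - raw.mean()) / sigma
        logz = np.log(z - z.min() + 1.0)
        span = logz.max() - logz.min()
        scaled = 10.0 * (logz - logz.min()) / span
        pct = percentile_rank(scaled)

    return pd.DataFrame(
        {
            "gene_symbol": genes,
            "raw": raw,
            "z": z,
            "logz": logz,
            "scaled": scaled,
            "percentile": pct,
        }
    )


def score_table(records: pd.DataFrame) -> pd.DataFrame:
    """Harmonized associations -> full score table (one row per gene)."""
    profiles = profiles_from_records(records)
    if not profiles:
        raise ValidationError("no genes to score: harmonized table is empty")
    return scale_scores([(p.gene_symbol, raw_score(p)) for p in profiles])
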