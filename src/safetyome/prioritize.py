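"""Target prioritization: tissue specificity, cross-species conservation, core panel.

Safetyome targets are ranked by three percentile-ranked metrics — the Tau
tissue-specificity index, a composite conservation score, and the 0-10
evidence score — combined (by default) as their unweighted mean. The top-N
targets (default 500) form the core panel used for routine screening.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

SPECIES = ("mouse", "rat", "dog")

CORE_COLUMNS = [
    "rank",
    "gene_symbol",
    "tau",
    "conservation",
    "scaled",
    "combined_rank_score",
]


def tau_index(expression: Sequence[float]) -> float:
    """Tau tissue-specificity index: sum(1 - x_i / x_max) / (N - 1).

    0 for perfectly uniform expression, 1 for expression confined to a
    single tissue. Undefined (NaN, with a warning) for an all-zero profile.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("tau_index requires a vector of >= 2 tissues")
    if (x < 0).any():
        raise ValidationError("expression values must be non-negative")
    xmax = x.max()
    if xmax == 0:
        logger.warning("all-zero expression vector: Tau is undefined")
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def tau_table(expression: pd.DataFrame) -> pd.Series:
    """Per-gene Tau from a genes x tissues matrix (genes as the index)."""
    if expression.shape[1] < 2:
        raise ValidationError("expression matrix needs >= 2 tissue columns")
    return pd.Series(
        {g: tau_index(row.to_numpy()) for g, row in expression.iterrows()},
        name="tau",
    )


def _pct_rank(s: pd.Series) -> pd.Series:
    # average-rank / N, in (0, 1]; ties share the average rank
    return s.rank(pct=True, method="average")


def conservation_score(records: pd.DataFrame) -> pd.Series:
    """Composite conservation score in [0, 1] per gene.

    Input is long-form (gene_symbol, species, identity_pct, confident).
    Per gene, the median across species is taken for each of the two
    metrics — primary-sequence identity to the preclinical species and
    ortholog-call confidence — the two medians are percentile-ranked
    across genes, and the score is the mean of the two ranks.
    """
    bad = set(records["species"]) - set(SPECIES)
    if bad:
        raise ValidationError(f"unknown species: {sorted(bad)}")
    med = records.groupby("gene_symbol")[["identity_pct", "confident"]].median()
    ranks = med.apply(_pct_rank)
    return ranks.mean(axis=1).rename("conservation")


def build_core_panel(
    scores: pd.DataFrame,
    tau: Mapping[str, float] | pd.Series,
    conservation: Mapping[str, float] | pd.Series,
    n: int = 500,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Rank targets by the weighted mean of three percentile ranks; keep top n.

    ``weights`` applies to (scaled score, tau, conservation) in that order.
    Genes missing tau or conservation contribute only their available
    metric ranks (weighted mean over present metrics) and stay in the
    ranking; ties in the combined score break by scaled score, then gene
    symbol. Returns fewer than n rows (with a warning) if the cohort is
    smaller than n.
    """
    if n < 1:
        raise ValidationError(f"core panel size must be >= 1, got {n}")
    df = scores[["gene_symbol", "scaled"]].copy()
    df["tau"] = df["gene_symbol"].map(dict(tau) if not isinstance(tau, dict) else tau)
    cons = dict(conservation) if not isinstance(conservation, dict) else conservation
    df["conservation"] = df["gene_symbol"].map(cons)

    metric_ranks = pd.DataFrame(
        {
            "scaled": _pct_rank(df["scaled"]),
            "tau": _pct_rank(df["tau"]),
            "conservation": _pct_rank(df["conservation"]),
        }
    )
    w = np.asarray(weights, dtype=float)
    weighted = metric_ranks.mul(w, axis=1)
    present_w = metric_ranks.notna().mul(w, axis=1).sum(axis=1)
    df["combined_rank_score"] = weighted.sum(axis=1, skipna=True) / present_w

    n_missing = int(metric_ranks.isna().any(axis=1).sum())
    if n_missing:
        logger.warning(
            "%d gene(s) missing tau and/or conservation; ranked on available metrics",
            n_missing,
        )
    df = df.sort_values(
        ["combined_rank_score", "scaled", "gene_symbol"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    if len(df) < n:
        logger.warning("cohort has %d genes; core panel smaller than n=%d", len(df), n)
    out = df.head(n).copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out[CORE_COLUMNS]
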