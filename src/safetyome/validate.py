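"""Orthogonal testing of panels against an independent disease–gene resource.

Each panel is treated as a query gene list and every disease's
direct-evidence gene set as a term; a one-sided hypergeometric
over-representation test is run per (panel, disease) pair, p-values are
adjusted per panel level (Benjamini-Hochberg at the organ level,
Bonferroni at the phenotype level, both configurable), and the *match
rate* of a panel is the percentage of its significantly enriched diseases
whose independently mapped SOC/PT label equals the panel's own label.
Phenotype-level testing is restricted to panels of at least 50 genes to
avoid instability from tiny sets.

The percentile cutoff sweep rebuilds the SOC safetyome at each evidence
cutoff from 10% to 90% and records the resulting size and mean match rate,
which is how the operating cutoff is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .panels import Panel, SafetyomeConfig, build_soc_safetyome

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "panel_id",
    "disease_term",
    "overlap",
    "panel_size",
    "disease_set_size",
    "universe_size",
    "p",
    "p_adj",
    "significant",
    "matched",
]


@dataclass(frozen=True)
class ValidateConfig:
    alpha: float = 0.05
    soc_adjust: str = "bh"
    pt_adjust: str = "bonferroni"
    min_panel_genes_pt: int = 50
    sweep_cutoffs: tuple[int, ...] = tuple(range(10, 100, 10))


def load_disease_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep only direct-evidence rows and deduplicate (disease, gene)."""
    direct = frame[frame["direct_evidence"].astype(int) == 1]
    return direct.drop_duplicates(subset=["disease_term", "gene_symbol"]).reset_index(
        drop=True
    )


def hypergeom_test(
    panel_genes: set[str], disease_genes: set[str], universe: set[str]
) -> float:
    """One-sided over-representation p-value, P(X >= observed overlap)."""
    if not universe:
        raise ValidationError("enrichment universe is empty")
    panel = panel_genes & universe
    disease = disease_genes & universe
    overlap = len(panel & disease)
    # survival function at overlap-1 gives P(X >= overlap)
    return float(hypergeom.sf(overlap - 1, len(universe), len(disease), len(panel)))


def adjust_pvalues(ps: Sequence[float], method: str = "bonferroni") -> list[float]:
    """Multiple-testing adjustment: Bonferroni or Benjamini-Hochberg step-up."""
    if len(ps) == 0:
        return []
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return list(multipletests(list(ps), method=key)[1])


def enrich_panels(
    panels: Iterable[Panel],
    disease_table: pd.DataFrame,
    disease_labels: Mapping[str, set[str]],
    level: str,
    cfg: ValidateConfig | None = None,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Test every (panel, disease) pair; adjust p-values across all tests.

    ``disease_labels`` maps each disease term to its mapped SOC or PT
    label(s) at the requested level; a pair is *matched* when the panel id
    is among the disease's labels. The universe defaults to all genes with
    direct disease evidence in the table.
    """
    cfg = cfg or ValidateConfig()
    table = load_disease_table(disease_table)
    if universe is None:
        universe = set(table["gene_symbol"])
    disease_sets = {
        str(d): set(grp["gene_symbol"]) for d, grp in table.groupby("disease_term")
    }
    tested = [
        p
        for p in panels
        if level != "PT" or len(p.genes) >= cfg.min_panel_genes_pt
    ]
    rows = []
    for panel in sorted(tested, key=lambda p: p.panel_id):
        for disease in sorted(disease_sets):
            genes = disease_sets[disease]
            p = hypergeom_test(panel.genes, genes, universe)
            rows.append(
                {
                    "panel_id": panel.panel_id,
                    "disease_term": disease,
                    "overlap": len(panel.genes & genes & universe),
                    "panel_size": len(panel.genes & universe),
                    "disease_set_size": len(genes & universe),
                    "universe_size": len(universe),
                    "p": p,
                }
            )
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:7])
    if out.empty:
        logger.warning("no (panel, disease) pairs were tested at level %s", level)
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    method = cfg.pt_adjust if level == "PT" else cfg.soc_adjust
    out["p_adj"] = adjust_pvalues(out["p"].tolist(), method)
    out["significant"] = out["p_adj"] < cfg.alpha
    out["matched"] = [
        r.panel_id in disease_labels.get(r.disease_term, set())
        for r in out.itertuples(index=False)
    ]
    return out


def match_rate(results: pd.DataFrame, level: str) -> tuple[pd.Series, float]:
    """Per-panel and mean match rates over significantly enriched diseases.

    Per panel: 100 * (# significant matched) / (# significant). The mean is
    over panels with at least one significant result; NaN (with a warning)
    when nothing is significant anywhere.
    """
    dup = results.duplicated(subset=["panel_id", "disease_term"])
    if dup.any():
        raise ValidationError("duplicate (panel, disease) enrichment rows")
    sig = results[results["significant"]]
    if sig.empty:
        logger.warning("no significant enrichments at level %s", level)
        return pd.Series(dtype=float, name="match_rate_pct"), float("nan")
    per_panel = (
        sig.groupby("panel_id")["matched"].mean().mul(100.0).rename("match_rate_pct")
    )
    return per_panel, float(per_panel.mean())


def cutoff_sweep(
    links: pd.DataFrame,
    scores: pd.DataFrame,
    disease_table: pd.DataFrame,
    disease_labels: Mapping[str, set[str]],
    panel_cfg: SafetyomeConfig,
    cfg: ValidateConfig | None = None,
) -> pd.DataFrame:
    """Rebuild SOC panels at each percentile cutoff and record the match rate.

    Returns one row per cutoff with the safetyome size and the mean
    SOC-level match rate at that cutoff. The sweep uses per-SOC percentile
    ranking by default via ``panel_cfg.percentile_scope``.
    """
    cfg = cfg or ValidateConfig()
    rows = []
    for cutoff in cfg.sweep_cutoffs:
        soc_panels, safetyome = build_soc_safetyome(
            links, scores, replace(panel_cfg, cutoff_percentile=float(cutoff))
        )
        results = enrich_panels(
            soc_panels, disease_table, disease_labels, level="SOC", cfg=cfg
        )
        _, mean_rate = match_rate(results, "SOC") if len(results) else (None, float("nan"))
        rows.append(
            {
                "cutoff_percentile": cutoff,
                "n_targets": len(safetyome),
                "match_rate_pct": mean_rate,
            }
        )
    return pd.DataFrame(rows)
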