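"""Assembly of organ-level (SOC) safetyome panels and phenotype-level (PT) panels.

The SOC-level safetyome keeps, per organ system, the linked genes whose
score percentile meets an evidence cutoff (default: the top half), after
removing the SOCs that do not name an actual organ system. The PT-level
specialized panels instead require each gene–phenotype pair to be supported
by at least ``min_sources`` distinct databases (default 2). Panels are
serialized as GMT gene sets plus a long-form TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .scoring import percentile_rank

PANEL_LEVELS = ("SOC", "PT")


@dataclass
class Panel:
    panel_id: str
    level: str
    support: dict[str, set[str]]
    evidence_classes: dict[str, set[str]] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.support)

    def gmt_description(self) -> str:
        sizes = [len(s) for s in self.support.values()] or [0]
        classes = sorted({c for cs in self.evidence_classes.values() for c in cs})
        return (
            f"level={self.level};sources={min(sizes)}-{max(sizes)};"
            f"classes={','.join(classes) if classes else 'none'}"
        )


@dataclass(frozen=True)
class SafetyomeConfig:
    excluded_socs: frozenset[str] = frozenset()
    cutoff_percentile: float = 50.0
    min_sources_pt: int = 2
    percentile_scope: str = "global"  # or "per_soc"

    def __post_init__(self) -> None:
        if not (0.0 <= self.cutoff_percentile <= 100.0):
            raise ValidationError(
                f"cutoff_percentile must lie in [0, 100], got {self.cutoff_percentile}"
            )
        if self.percentile_scope not in ("global", "per_soc"):
            raise ValidationError(
                f"percentile_scope must be 'global' or 'per_soc', "
                f"got {self.percentile_scope!r}"
            )


def _panels_from_links(links: pd.DataFrame, level: str, key: str) -> list[Panel]:
    panels: list[Panel] = []
    for panel_id, grp in links.groupby(key, sort=True):
        support: dict[str, set[str]] = {}
        classes: dict[str, set[str]] = {}
        for rec in grp.itertuples(index=False):
            support.setdefault(rec.gene_symbol, set()).add(rec.source_id)
            classes.setdefault(rec.gene_symbol, set()).add(rec.evidence_class)
        panels.append(Panel(str(panel_id), level, support, classes))
    return panels


def build_soc_safetyome(
    links: pd.DataFrame,
    scores: pd.DataFrame,
    cfg: SafetyomeConfig,
) -> tuple[list[Panel], set[str]]:
    """One panel per retained SOC plus the safetyome (union of panel genes).

    Links to excluded SOCs are dropped, then genes whose score percentile is
    at or above the cutoff are retained. With ``percentile_scope="global"``
    the percentile is the cohort-wide rank from the score table; with
    ``"per_soc"`` scaled scores are re-ranked within each SOC's linked genes
    before applying the same cutoff.
    """
    kept = links[~links["soc_term"].isin(cfg.excluded_socs)]
    scored = set(scores["gene_symbol"])
    missing = set(kept["gene_symbol"]) - scored
    if missing:
        raise ValidationError(
            f"{len(missing)} linked gene(s) have no score, e.g. {sorted(missing)[:3]}"
        )
    if cfg.percentile_scope == "global":
        pct = dict(zip(scores["gene_symbol"], scores["percentile"]))
        kept = kept[kept["gene_symbol"].map(pct) >= cfg.cutoff_percentile]
    else:
        scaled = dict(zip(scores["gene_symbol"], scores["scaled"]))
        parts = []
        for _, grp in kept.groupby("soc_term", sort=True):
            genes = sorted(set(grp["gene_symbol"]))
            pcts = dict(zip(genes, percentile_rank([scaled[g] for g in genes])))
            parts.append(grp[grp["gene_symbol"].map(pcts) >= cfg.cutoff_percentile])
        kept = (
            pd.concat(parts, ignore_index=True)
            if parts
            else kept.iloc[0:0]
        )
    panels = _panels_from_links(kept, "SOC", "soc_term")
    safetyome = set().union(*(p.genes for p in panels)) if panels else set()
    return panels, safetyome


def build_pt_panels(links: pd.DataFrame, min_sources: int = 2) -> list[Panel]:
    """Phenotype panels keeping genes supported by >= min_sources databases."""
    if min_sources < 1:
        raise ValidationError(f"min_sources must be >= 1, got {min_sources}")
    panels: list[Panel] = []
    for panel in _panels_from_links(links, "PT", "pt_term"):
        support = {g: s for g, s in panel.support.items() if len(s) >= min_sources}
        if not support:
            continue
        classes = {g: panel.evidence_classes[g] for g in support}
        panels.append(Panel(panel.panel_id, "PT", support, classes))
    return panels


def summarize(panels: list[Panel], links: pd.DataFrame) -> dict:
    """Descriptive tallies of the panel collection.

    Returns per-panel unique gene counts, the genetics / pharmacology /
    both split of panel genes, the histogram of distinct SOCs per gene
    (from the link table), and the fraction of gene–SOC associations
    supported by more than one source.
    """
    per_panel = {p.panel_id: len(p.genes) for p in panels}
    class_split = {"genetic_only": 0, "pharmacological_only": 0, "both": 0}
    merged: dict[str, set[str]] = {}
    for p in panels:
        for g, cs in p.evidence_classes.items():
            merged.setdefault(g, set()).update(cs)
    for cs in merged.values():
        if cs == {"genetic"}:
            class_split["genetic_only"] += 1
        elif cs == {"pharmacological"}:
            class_split["pharmacological_only"] += 1
        else:
            class_split["both"] += 1
    socs_per_gene = (
        links.groupby("gene_symbol")["soc_term"].nunique()
        if len(links)
        else pd.Series(dtype=int)
    )
    histogram = {int(k): int(v) for k, v in socs_per_gene.value_counts().items()}
    gene_soc_sources = (
        links.groupby(["gene_symbol", "soc_term"])["source_id"].nunique()
        if len(links)
        else pd.Series(dtype=int)
    )
    multi = float((gene_soc_sources > 1).mean()) if len(gene_soc_sources) else 0.0
    return {
        "per_panel_gene_counts": per_panel,
        "evidence_class_split": class_split,
        "soc_count_histogram": dict(sorted(histogram.items())),
        "multi_source_gene_soc_fraction": multi,
    }


def write_gmt(panels: Iterable[Panel], path: str | Path) -> None:
    """Write panels as GMT: name <tab> description <tab> gene1 <tab> ..."""
    with open(path, "w") as fh:
        for p in sorted(panels, key=lambda p: p.panel_id):
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.panel_id}\t{p.gmt_description()}\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2 and fields[0]:
                sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def panels_long_form(panels: Iterable[Panel]) -> pd.DataFrame:
    rows = [
        (
            p.panel_id,
            p.level,
            g,
            ",".join(sorted(p.support[g])),
            ",".join(sorted(p.evidence_classes.get(g, set()))),
        )
        for p in sorted(panels, key=lambda p: p.panel_id)
        for g in sorted(p.genes)
    ]
    return pd.DataFrame(
        rows, columns=["panel_id", "level", "gene_symbol", "sources", "evidence_classes"]
    )
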