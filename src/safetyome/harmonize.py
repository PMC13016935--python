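"""Harmonization of per-source gene–trait association tables.

Each of the nine evidence databases arrives as a normalized TSV with a
source-specific subset of the raw-record schema (p-value, effect validity,
association type, sub-source). A registered filter *policy* per source
applies that database's retention rules:

``gwas_like``
    keep records with a present p-value at or below the genome-wide
    significance threshold (default 5e-8, inclusive) and a valid effect
    estimate (odds ratio or beta present);
``clinvar_like``
    drop records whose sub-source annotation is missing or "NA";
``disgenet_like``
    keep only whitelisted genetic association types from whitelisted
    human-genetics sub-sources;
``passthrough``
    no record-level filter.

After per-source filtering, records are restricted to the protein-coding
gene universe, deduplicated on (gene, trait, source) and tagged with their
source's evidence class (genetic or pharmacological).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, SchemaError

EVIDENCE_CLASSES = ("genetic", "pharmacological")
RECORD_COLUMNS = ["gene_symbol", "trait_text", "source_id", "evidence_class"]

#: Association types counted as human genetic evidence.
DEFAULT_DISGENET_TYPES = frozenset(
    {
        "CausalMutation",
        "GermlineCausalMutation",
        "SomaticCausalMutation",
        "SusceptibilityMutation",
        "ModifyingMutation",
        "GeneticVariation",
    }
)

#: Sub-sources capturing human genetic evidence.
DEFAULT_DISGENET_SOURCES = frozenset(
    {"ClinGen", "ClinVar", "Genomics England", "GWAS Catalog", "GWASDB", "HPO", "Orphanet"}
)

POLICIES = ("gwas_like", "clinvar_like", "disgenet_like", "passthrough")


@dataclass(frozen=True)
class FilterConfig:
    gwas_p_threshold: float = 5e-8
    clinvar_excluded_sub_sources: frozenset[str] = frozenset({"NA"})
    disgenet_allowed_types: frozenset[str] = DEFAULT_DISGENET_TYPES
    disgenet_allowed_sources: frozenset[str] = DEFAULT_DISGENET_SOURCES
    require_protein_coding: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.gwas_p_threshold < 1.0):
            raise ConfigurationError(
                f"gwas_p_threshold must lie in (0, 1), got {self.gwas_p_threshold}"
            )


@dataclass
class SourceTable:
    """One database's normalized records plus its filter policy."""

    source_id: str
    evidence_class: str
    policy: str
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.source_id:
            raise ConfigurationError("source_id must be non-empty")
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ConfigurationError(
                f"{self.source_id}: evidence_class must be one of {EVIDENCE_CLASSES}"
            )


def _require(records: pd.DataFrame, columns: list[str], policy: str) -> None:
    missing = [c for c in columns if c not in records.columns]
    if missing:
        raise SchemaError(f"{policy} filter requires missing column(s): {missing}")


def filter_gwas_like(records: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Inclusive p <= threshold with a valid effect estimate; order preserved."""
    _require(records, ["p_value", "effect_ok"], "gwas_like")
    p = pd.to_numeric(records["p_value"], errors="coerce")
    ok = records["effect_ok"].fillna(False).astype(bool)
    return records[p.notna() & (p <= cfg.gwas_p_threshold) & ok]


def filter_clinvar_like(records: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Drop records lacking sub-source provenance (missing counts as "NA")."""
    _require(records, ["sub_source"], "clinvar_like")
    sub = records["sub_source"].fillna("NA").astype(str).str.strip()
    excluded = set(cfg.clinvar_excluded_sub_sources) | {""}
    return records[~sub.isin(excluded)]


def filter_disgenet_like(records: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep whitelisted genetic association types from whitelisted sub-sources."""
    _require(records, ["association_type", "sub_source"], "disgenet_like")
    typ_ok = records["association_type"].isin(cfg.disgenet_allowed_types)
    src_ok = records["sub_source"].isin(cfg.disgenet_allowed_sources)
    return records[typ_ok & src_ok]


_POLICY_FUNCS = {
    "gwas_like": filter_gwas_like,
    "clinvar_like": filter_clinvar_like,
    "disgenet_like": filter_disgenet_like,
    "passthrough": lambda records, cfg: records,
}


def apply_policy(table: SourceTable, cfg: FilterConfig) -> pd.DataFrame:
    func = _POLICY_FUNCS.get(table.policy)
    if func is None:
        raise ConfigurationError(
            f"source {table.source_id!r}: unknown filter policy {table.policy!r}; "
            f"expected one of {POLICIES}"
        )
    return func(table.frame, cfg)


def harmonize_all(
    tables: list[SourceTable],
    gene_universe: pd.DataFrame | None = None,
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Filter, restrict to protein-coding genes, deduplicate and tag all sources.

    Returns the harmonized association table (gene_symbol, trait_text,
    source_id, evidence_class), unique on (gene, trait, source). Gene
    symbols are matched case-sensitively after whitespace trimming.
    """
    cfg = cfg or FilterConfig()
    seen_ids: set[str] = set()
    parts: list[pd.DataFrame] = []
    for table in tables:
        if table.source_id in seen_ids:
            raise ConfigurationError(f"duplicate source_id {table.source_id!r}")
        seen_ids.add(table.source_id)
        kept = apply_policy(table, cfg)
        _require(kept, ["gene_symbol", "trait_text"], table.policy)
        part = kept[["gene_symbol", "trait_text"]].copy()
        part["gene_symbol"] = part["gene_symbol"].astype(str).str.strip()
        part["trait_text"] = part["trait_text"].astype(str)
        part["source_id"] = table.source_id
        part["evidence_class"] = table.evidence_class
        parts.append(part)

    out = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=RECORD_COLUMNS)
    )
    if cfg.require_protein_coding:
        if gene_universe is None:
            raise ConfigurationError(
                "require_protein_coding is set but no gene universe was supplied"
            )
        _require(gene_universe, ["gene_symbol", "biotype"], "gene universe")
        coding = set(
            gene_universe.loc[
                gene_universe["biotype"] == "protein_coding", "gene_symbol"
            ].astype(str).str.strip()
        )
        out = out[out["gene_symbol"].isin(coding)]
    out = out.drop_duplicates(subset=["gene_symbol", "trait_text", "source_id"])
    return out.sort_values(RECORD_COLUMNS[:3], ignore_index=True)[RECORD_COLUMNS]
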