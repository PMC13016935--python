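"""Synthetic evidence world with planted ground truth.

Generates, from one seed, every input the pipeline consumes: a two-level
term hierarchy with a synonym lexicon, nine source association tables
(seven genetic, two pharmacological) with source-specific columns and
deliberately filterable junk rows, an independent disease–gene table, a
gene x tissue expression matrix, a cross-species orthology table and a
gene universe with biotypes. The generator records the ground truth it
planted — true gene–phenotype assignments, per-association source
membership, the high-priority core gene set and each disease's phenotype
label — so recovery can be measured exactly.

Noise is explicit and independently tunable: ``trait_noise_rate`` perturbs
trait surface forms (adjacent-character swaps plus optional suffix tokens)
so that exact lexicon lookup fails and the fuzzy/embedding stages are
genuinely exercised; ``assoc_dropout`` removes true evidence records;
``disease_noise_rate`` swaps disease genes for random ones. All synthetic
vocabularies use opaque labels (SOC_01, PT_0042, GENE0001) — no real
terminology strings are fabricated.

Structural guarantees used by the tests:

* at zero trait noise every emitted trait is verbatim from the lexicon, so
  the cascade maps 100% of traits at the exact stage;
* junk rows are constructed to fail their source's filter, so the
  harmonized table equals the recorded true association table exactly;
* each disease's genes are drawn from genes exclusive to one organ system,
  so at zero disease noise the organ-level match rate is 100%;
* planted core genes dominate evidence breadth, tissue specificity and
  conservation simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .harmonize import (
    DEFAULT_DISGENET_SOURCES,
    DEFAULT_DISGENET_TYPES,
    SourceTable,
)

RAW_COLUMNS = [
    "gene_symbol",
    "trait_text",
    "p_value",
    "effect_ok",
    "association_type",
    "sub_source",
]

#: (source_id, evidence_class, policy) — seven genetic plus two pharmacological.
SOURCE_SPECS: tuple[tuple[str, str, str], ...] = (
    ("src_gwas", "genetic", "gwas_like"),
    ("src_pgi", "genetic", "gwas_like"),
    ("src_clinvar", "genetic", "clinvar_like"),
    ("src_disgenet", "genetic", "disgenet_like"),
    ("src_hpo", "genetic", "passthrough"),
    ("src_litmine", "genetic", "passthrough"),
    ("src_opentargets", "genetic", "passthrough"),
    ("src_drugbank", "pharmacological", "passthrough"),
    ("src_ttd", "pharmacological", "passthrough"),
)

_CLINVAR_SUBSOURCES = ("OMIM", "Orphanet", "GeneReviews", "MONDO", "NCBI curation")
_SYNONYM_SUFFIXES = ("", " condition", " syndrome", " disorder", " disease")


@dataclass(frozen=True)
class WorldConfig:
    n_genes: int = 1000
    n_socs: int = 27
    n_nonorgan_socs: int = 5
    pts_per_soc: int = 8
    synonyms_per_concept: int = 3
    multi_pt_fraction: float = 0.1
    multi_source_fraction: float = 0.6
    trait_noise_rate: float = 0.1
    assoc_dropout: float = 0.05
    disease_noise_rate: float = 0.1
    n_core_truth: int = 50
    n_tissues: int = 30
    diseases_per_soc: int = 3
    disease_size: int = 20
    junk_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "multi_pt_fraction",
            "multi_source_fraction",
            "trait_noise_rate",
            "assoc_dropout",
            "disease_noise_rate",
            "junk_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_nonorgan_socs >= self.n_socs:
            raise ValidationError("need at least one organ SOC")
        if self.pts_per_soc < self.diseases_per_soc:
            raise ValidationError(
                "pts_per_soc must be >= diseases_per_soc so each disease "
                "gets a distinct phenotype label"
            )
        if self.synonyms_per_concept < 1 or self.synonyms_per_concept > len(
            _SYNONYM_SUFFIXES
        ):
            raise ValidationError(
                f"synonyms_per_concept must be in 1..{len(_SYNONYM_SUFFIXES)}"
            )
        if self.n_core_truth > self.n_genes:
            raise ValidationError("n_core_truth cannot exceed n_genes")


@dataclass
class GroundTruth:
    excluded_socs: frozenset[str]
    assoc_records: pd.DataFrame  # expected harmonized output
    pt_support: dict[tuple[str, str], set[str]]  # (gene, pt) -> sources
    gene_to_ptsoc: dict[str, set[tuple[str, str]]]
    core_genes: frozenset[str]
    disease_labels: dict[str, tuple[str, str]]  # disease -> (pt, soc)

    def pt_panels(self, min_sources: int = 2) -> dict[str, set[str]]:
        """True PT-level panels under the >= min_sources evidence rule."""
        out: dict[str, set[str]] = {}
        for (gene, pt), sources in self.pt_support.items():
            if len(sources) >= min_sources:
                out.setdefault(pt, set()).add(gene)
        return out


@dataclass
class World:
    config: WorldConfig
    hierarchy: pd.DataFrame
    tables: list[SourceTable]
    disease_table: pd.DataFrame
    expression: pd.DataFrame
    orthology: pd.DataFrame
    gene_universe: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize every input as TSV plus a sources.yaml column map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _tsv(name: str, frame: pd.DataFrame, **kw) -> Path:
            p = outdir / f"{name}.tsv"
            frame.to_csv(p, sep="\t", index=kw.pop("index", False), **kw)
            paths[name] = p
            return p

        _tsv("hierarchy", self.hierarchy)
        _tsv("disease_genes", self.disease_table)
        _tsv("expression", self.expression, index=True)
        _tsv("orthology", self.orthology)
        _tsv("gene_universe", self.gene_universe)
        sources_meta = {}
        for t in self.tables:
            _tsv(t.source_id, t.frame)
            sources_meta[t.source_id] = {
                "path": f"{t.source_id}.tsv",
                "evidence_class": t.evidence_class,
                "policy": t.policy,
                "columns": {c: c for c in RAW_COLUMNS},
            }
        with open(outdir / "sources.yaml", "w") as fh:
            yaml.safe_dump({"sources": sources_meta}, fh, sort_keys=True)
        paths["sources"] = outdir / "sources.yaml"
        with open(outdir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "excluded_socs": sorted(self.truth.excluded_socs),
                    "core_genes": sorted(self.truth.core_genes),
                    "disease_labels": {
                        d: list(v) for d, v in sorted(self.truth.disease_labels.items())
                    },
                },
                fh,
                sort_keys=True,
            )
        paths["ground_truth"] = outdir / "ground_truth.yaml"
        return paths


def _perturb(trait: str, rng: np.random.Generator) -> str:
    """Break exact/partial lexicon matching with in-token character swaps."""

    def swap(tok: str) -> str:
        if len(tok) < 2:
            return tok + "q"
        for i in range(len(tok) - 1):
            if tok[i] != tok[i + 1]:
                return tok[:i] + tok[i + 1] + tok[i] + tok[i + 2 :]
        return tok + "q"

    tokens = trait.split()
    tokens[0] = swap(tokens[0])
    if len(tokens) > 1:
        tokens[1] = swap(tokens[1])
    if rng.random() < 0.5:
        tokens.append(f"x{rng.integers(10, 100)}q")
    return " ".join(tokens)


def generate_world(cfg: WorldConfig | None = None) -> World:
    """Build the full synthetic world deterministically from ``cfg.seed``."""
    cfg = cfg or WorldConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    n_nc = max(10, cfg.n_genes // 20)
    noncoding = [f"NCG{i + 1:04d}" for i in range(n_nc)]
    universe = pd.DataFrame(
        {
            "gene_symbol": genes + noncoding,
            "biotype": ["protein_coding"] * len(genes) + ["lncRNA"] * n_nc,
        }
    )

    socs = [f"SOC_{i + 1:02d}" for i in range(cfg.n_socs)]
    organ_socs = socs[: cfg.n_socs - cfg.n_nonorgan_socs]
    excluded = frozenset(socs[cfg.n_socs - cfg.n_nonorgan_socs :])

    # hierarchy: one primary concept per PT; a fraction of concepts carry a
    # second (PT, SOC) pair within the same SOC to exercise multi-PT fan-out
    n_concepts = cfg.n_socs * cfg.pts_per_soc
    concept_pairs: dict[str, list[tuple[str, str]]] = {}
    concept_syns: dict[str, list[str]] = {}
    concepts_by_soc: dict[str, list[str]] = {s: [] for s in socs}
    for i in range(n_concepts):
        cid = f"C{i + 1:04d}"
        pt = f"PT_{i + 1:04d}"
        soc = socs[i // cfg.pts_per_soc]
        concept_pairs[cid] = [(pt, soc)]
        concepts_by_soc[soc].append(cid)
        base = f"pheno {i + 1:04d}"
        concept_syns[cid] = [
            base + _SYNONYM_SUFFIXES[k] for k in range(cfg.synonyms_per_concept)
        ]
    for i in range(n_concepts):
        last_in_soc = (i + 1) % cfg.pts_per_soc == 0
        if not last_in_soc and rng.random() < cfg.multi_pt_fraction:
            cid = f"C{i + 1:04d}"
            concept_pairs[cid].append((f"PT_{i + 2:04d}", socs[i // cfg.pts_per_soc]))
    hierarchy = pd.DataFrame(
        [
            (cid, syn, pt, soc)
            for cid in sorted(concept_pairs)
            for syn in concept_syns[cid]
            for pt, soc in concept_pairs[cid]
        ],
        columns=["concept_id", "synonym", "pt_term", "soc_term"],
    )

    # gene -> concept assignments. Pleiotropy is limited: each gene gets a
    # primary SOC and draws most concepts from it, occasionally reaching
    # into other systems. Planted core genes get broad organ coverage.
    core_genes = frozenset(
        rng.choice(genes, size=cfg.n_core_truth, replace=False).tolist()
    )
    all_concepts = sorted(concept_pairs)
    organ_concepts = sorted(c for s in organ_socs for c in concepts_by_soc[s])
    assignments: dict[str, list[str]] = {}
    for g in genes:
        if g in core_genes:
            k = min(8, len(organ_concepts))
            assignments[g] = sorted(
                rng.choice(organ_concepts, size=k, replace=False).tolist()
            )
        elif rng.random() < 0.9:
            primary = socs[rng.integers(cfg.n_socs)]
            k = min(1 + rng.poisson(1.2), 5)
            chosen: set[str] = set()
            for _ in range(k):
                pool = (
                    concepts_by_soc[primary]
                    if rng.random() < 0.7
                    else all_concepts
                )
                chosen.add(pool[rng.integers(len(pool))])
            assignments[g] = sorted(chosen)

    source_ids = [s for s, _, _ in SOURCE_SPECS]
    genetic_ids = [s for s, c, _ in SOURCE_SPECS if c == "genetic"]

    # true records per source: (gene, concept) -> supporting sources -> rows
    true_rows: dict[str, list[dict]] = {s: [] for s in source_ids}
    pt_support: dict[tuple[str, str], set[str]] = {}
    gene_to_ptsoc: dict[str, set[tuple[str, str]]] = {}
    for g in sorted(assignments):
        for cid in assignments[g]:
            if g in core_genes:
                chosen = list(rng.choice(source_ids, size=7, replace=False))
                n_records = 2
            else:
                if rng.random() < cfg.multi_source_fraction:
                    m = int(rng.integers(2, 5))
                else:
                    m = 1
                chosen = list(rng.choice(source_ids, size=m, replace=False))
                n_records = 1
            for src in sorted(chosen):
                for _ in range(n_records):
                    if rng.random() < cfg.assoc_dropout:
                        continue
                    syn = concept_syns[cid][rng.integers(len(concept_syns[cid]))]
                    trait = (
                        _perturb(syn, rng)
                        if rng.random() < cfg.trait_noise_rate
                        else syn
                    )
                    true_rows[src].append(_true_row(src, g, trait, rng))
                    for pt, soc in concept_pairs[cid]:
                        pt_support.setdefault((g, pt), set()).add(src)
                        gene_to_ptsoc.setdefault(g, set()).add((pt, soc))

    all_syns = [s for c in sorted(concept_syns) for s in concept_syns[c]]
    tables: list[SourceTable] = []
    truth_records: list[tuple[str, str, str, str]] = []
    for src, ev_class, policy in SOURCE_SPECS:
        rows = true_rows[src]
        n_junk = max(2, int(cfg.junk_fraction * max(len(rows), 1)))
        junk = [
            _junk_row(policy, genes, noncoding, all_syns, rng) for _ in range(n_junk)
        ]
        frame = pd.DataFrame(rows + junk, columns=RAW_COLUMNS)
        tables.append(SourceTable(src, ev_class, policy, frame))
        seen: set[tuple[str, str]] = set()
        for r in rows:
            key = (r["gene_symbol"], r["trait_text"])
            if key not in seen:
                seen.add(key)
                truth_records.append(key + (src, ev_class))
    assoc_records = (
        pd.DataFrame(
            truth_records,
            columns=["gene_symbol", "trait_text", "source_id", "evidence_class"],
        )
        .sort_values(["gene_symbol", "trait_text", "source_id"], ignore_index=True)
    )

    disease_table, disease_labels = _diseases(
        cfg, rng, organ_socs, concepts_by_soc, concept_pairs, concept_syns,
        gene_to_ptsoc, pt_support, sorted(assignments),
    )

    tissues = [f"T{i + 1:02d}" for i in range(cfg.n_tissues)]
    expr = rng.gamma(2.0, 10.0, size=(len(genes), cfg.n_tissues))
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_symbol"),
                              columns=tissues)
    for g in sorted(core_genes):
        row = np.zeros(cfg.n_tissues)
        row[rng.integers(cfg.n_tissues)] = float(rng.uniform(50, 150))
        expression.loc[g] = row

    ortho_rows = []
    for g in genes:
        is_core = g in core_genes
        for sp in ("mouse", "rat", "dog"):
            identity = 99.0 if is_core else float(np.round(rng.uniform(40, 95), 2))
            confident = 1 if is_core else int(rng.random() < 0.7)
            ortho_rows.append((g, sp, identity, confident))
    orthology = pd.DataFrame(
        ortho_rows, columns=["gene_symbol", "species", "identity_pct", "confident"]
    )

    truth = GroundTruth(
        excluded_socs=excluded,
        assoc_records=assoc_records,
        pt_support=pt_support,
        gene_to_ptsoc=gene_to_ptsoc,
        core_genes=core_genes,
        disease_labels=disease_labels,
    )
    return World(
        config=cfg,
        hierarchy=hierarchy,
        tables=tables,
        disease_table=disease_table,
        expression=expression,
        orthology=orthology,
        gene_universe=universe,
        truth=truth,
    )


def _true_row(src: str, gene: str, trait: str, rng: np.random.Generator) -> dict:
    row = {
        "gene_symbol": gene,
        "trait_text": trait,
        "p_value": np.nan,
        "effect_ok": True,
        "association_type": "",
        "sub_source": "",
    }
    if src in ("src_gwas", "src_pgi"):
        row["p_value"] = float(10.0 ** -rng.uniform(8.0, 30.0))
    elif src == "src_clinvar":
        row["sub_source"] = _CLINVAR_SUBSOURCES[rng.integers(len(_CLINVAR_SUBSOURCES))]
    elif src == "src_disgenet":
        types = sorted(DEFAULT_DISGENET_TYPES)
        subs = sorted(DEFAULT_DISGENET_SOURCES)
        row["association_type"] = types[rng.integers(len(types))]
        row["sub_source"] = subs[rng.integers(len(subs))]
    return row


def _junk_row(
    policy: str,
    genes: list[str],
    noncoding: list[str],
    synonyms: list[str],
    rng: np.random.Generator,
) -> dict:
    """A record guaranteed to be removed by its source's filter."""
    trait = synonyms[rng.integers(len(synonyms))]
    row = {
        "gene_symbol": genes[rng.integers(len(genes))],
        "trait_text": trait,
        "p_value": np.nan,
        "effect_ok": True,
        "association_type": "",
        "sub_source": "",
    }
    if policy == "gwas_like":
        mode = rng.integers(3)
        if mode == 0:
            row["p_value"] = float(10.0 ** -rng.uniform(0.0, 7.0))  # above threshold
        elif mode == 1:
            row["p_value"] = np.nan  # missing p
        else:
            row["p_value"] = float(10.0 ** -rng.uniform(8.0, 20.0))
            row["effect_ok"] = False  # invalid effect estimate
    elif policy == "clinvar_like":
        row["sub_source"] = "NA"
    elif policy == "disgenet_like":
        if rng.random() < 0.5:
            row["association_type"] = "Biomarker"
            row["sub_source"] = "ClinVar"
        else:
            row["association_type"] = "GeneticVariation"
            row["sub_source"] = "UnlistedDB"
    else:  # passthrough junk: non-coding gene, removed by the biotype filter
        row["gene_symbol"] = noncoding[rng.integers(len(noncoding))]
    return row


def _diseases(
    cfg: WorldConfig,
    rng: np.random.Generator,
    organ_socs: list[str],
    concepts_by_soc: dict[str, list[str]],
    concept_pairs: dict[str, list[tuple[str, str]]],
    concept_syns: dict[str, list[str]],
    gene_to_ptsoc: dict[str, set[tuple[str, str]]],
    pt_support: dict[tuple[str, str], set[str]],
    participating: list[str],
) -> tuple[pd.DataFrame, dict[str, tuple[str, str]]]:
    """Disease gene sets drawn from each organ system's best-evidenced
    exclusive genes (a curated disease resource lists established genes),
    labelled via a synonym of one of that SOC's concepts so the label maps
    back to it. Noise swaps genes for ones from a single *contaminant*
    organ system, so noisy diseases drift towards the wrong panel."""
    soc_of = {g: {s for _, s in pairs} for g, pairs in gene_to_ptsoc.items()}
    evidence = {g: 0 for g in soc_of}
    for (g, _pt), sources in pt_support.items():
        evidence[g] += len(sources)
    pools: dict[str, list[str]] = {}
    for soc in organ_socs:
        exclusive = sorted(g for g, ss in soc_of.items() if ss == {soc})
        exclusive.sort(key=lambda g: (-evidence[g], g))
        pools[soc] = exclusive[: max(cfg.disease_size, int(0.6 * len(exclusive)))]
    usable = [s for s in organ_socs if len(pools[s]) >= 5]
    rows: list[tuple[str, str, int]] = []
    labels: dict[str, tuple[str, str]] = {}
    for soc in usable:
        for d in range(cfg.diseases_per_soc):
            cid = concepts_by_soc[soc][d]
            term = concept_syns[cid][0]
            pt, _ = concept_pairs[cid][0]
            if term in labels:
                continue
            labels[term] = (pt, soc)
            others = [s for s in usable if s != soc]
            contaminant = others[rng.integers(len(others))] if others else soc
            size = min(cfg.disease_size, len(pools[soc]))
            chosen = list(rng.choice(pools[soc], size=size, replace=False))
            for g in chosen:
                if rng.random() < cfg.disease_noise_rate:
                    pool = pools[contaminant]
                    g = pool[rng.integers(len(pool))]
                rows.append((term, g, 1))
    # indirect-evidence rows that the loader must discard
    n_indirect = max(2, len(rows) // 20)
    terms = sorted(labels)
    for _ in range(n_indirect):
        if not terms:
            break
        term = terms[rng.integers(len(terms))]
        g = participating[rng.integers(len(participating))]
        rows.append((term, g, 0))
    frame = pd.DataFrame(
        rows, columns=["disease_term", "gene_symbol", "direct_evidence"]
    ).drop_duplicates(subset=["disease_term", "gene_symbol"], keep="first")
    return frame.reset_index(drop=True), labels
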