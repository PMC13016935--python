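"""Free-text trait mapping onto a two-level safety ontology.

Traits are mapped to concepts of a user-supplied hierarchy with two levels:
a system organ class (SOC, the organ level) and preferred terms (PT, the
specific phenotype level); a concept expands to one or more (PT, SOC) pairs
and all of them are retained rather than forcing a single label.

Mapping is a three-stage cascade in a fixed order:

1. ``exact``     — lookup of the normalized trait in the synonym lexicon,
                   plus partial matching by substring containment (longest
                   synonym wins); similarity is 1 by definition.
2. ``fuzzy``     — a fuzzy string matcher over the lexicon, accepted at or
                   above ``fuzzy_min_score``.
3. ``embedding`` — a vector-similarity matcher over the lexicon, accepted
                   at or above ``embedding_threshold`` (inclusive).

The first stage that produces an accepted candidate wins, and only the
top-ranked candidate of that stage is kept; equal-similarity ties go to the
lexicographically smallest concept id so reruns are reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .matchers import CharTfidfEmbedder, TokenSetFuzzyMatcher

STAGES = ("exact", "fuzzy", "embedding")

_PUNCT = re.compile(r"[^0-9a-z]+")

LINK_COLUMNS = [
    "gene_symbol",
    "pt_term",
    "soc_term",
    "source_id",
    "evidence_class",
    "stage",
    "similarity",
]


def normalize_term(text: str) -> str:
    """Lowercase, strip punctuation to spaces, collapse whitespace, trim."""
    return _PUNCT.sub(" ", text.lower()).strip()


class Matcher(Protocol):
    """Contract for injectable stage-2/3 backends."""

    def candidates(self, text: str) -> list[tuple[str, float]]:
        """Return (concept_id, similarity) ranked by descending similarity."""
        ...


@dataclass(frozen=True)
class MapperConfig:
    embedding_threshold: float = 0.7
    fuzzy_min_score: float = 0.85
    stage_order: tuple[str, ...] = STAGES


@dataclass
class Hierarchy:
    """Two-level term hierarchy with a synonym lexicon.

    ``pt_of`` maps every concept to its (PT, SOC) pairs; ``synonyms`` maps a
    normalized surface string to exactly one concept (collisions resolved to
    the smallest concept id at load time).
    """

    pt_of: dict[str, frozenset[tuple[str, str]]]
    synonyms: dict[str, str]
    soc_terms: frozenset[str]

    @property
    def concepts(self) -> frozenset[str]:
        return frozenset(self.pt_of)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Hierarchy":
        required = {"concept_id", "synonym", "pt_term", "soc_term"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"hierarchy table missing columns: {sorted(missing)}")
        pt_of: dict[str, set[tuple[str, str]]] = {}
        synonyms: dict[str, str] = {}
        for row in frame.itertuples(index=False):
            cid = str(row.concept_id)
            pt_of.setdefault(cid, set()).add((str(row.pt_term), str(row.soc_term)))
            surface = normalize_term(str(row.synonym))
            if not surface:
                continue
            prev = synonyms.get(surface)
            if prev is None or cid < prev:
                synonyms[surface] = cid
        socs = frozenset(s for pairs in pt_of.values() for _, s in pairs)
        return cls(
            pt_of={c: frozenset(p) for c, p in pt_of.items()},
            synonyms=synonyms,
            soc_terms=socs,
        )

    @classmethod
    def from_tsv(cls, path) -> "Hierarchy":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


@dataclass(frozen=True)
class MappedPhenotype:
    trait_text: str
    concept_id: str
    pt_soc_pairs: frozenset[tuple[str, str]]
    stage: str
    similarity: float


@dataclass
class CoverageReport:
    per_stage_counts: dict[str, int]
    n_total: int
    n_unmapped: int
    top_unmapped: list[tuple[str, int]]
    per_source_unmapped_fraction: dict[str, float] = field(default_factory=dict)

    def to_yaml(self) -> str:
        payload = {
            "n_distinct_traits": self.n_total,
            "n_unmapped": self.n_unmapped,
            "per_stage_counts": {s: self.per_stage_counts.get(s, 0) for s in STAGES},
            "per_source_unmapped_fraction": {
                k: round(v, 6)
                for k, v in sorted(self.per_source_unmapped_fraction.items())
            },
            "top_unmapped": [list(t) for t in self.top_unmapped],
        }
        return yaml.safe_dump(payload, sort_keys=True)


def _lexicon_match(trait: str, hierarchy: Hierarchy) -> str | None:
    """Stage-1 exact or partial (substring containment) lexicon lookup."""
    hit = hierarchy.synonyms.get(trait)
    if hit is not None:
        return hit
    if not trait:
        return None
    best: tuple[int, str, str] | None = None  # (len, synonym, concept)
    for syn, cid in hierarchy.synonyms.items():
        if syn in trait or trait in syn:
            key = (len(syn), syn, cid)
            if best is None or key[0] > best[0] or (key[0] == best[0] and cid < best[2]):
                best = key
    return best[2] if best else None


def map_cascade(
    traits: Sequence[str],
    hierarchy: Hierarchy,
    fuzzy: Matcher | None = None,
    embedder: Matcher | None = None,
    cfg: MapperConfig | None = None,
) -> tuple[list[MappedPhenotype], list[str], CoverageReport]:
    """Map traits through the exact → fuzzy → embedding cascade.

    Traits are deduplicated on their normalized form before mapping; the
    coverage report counts distinct normalized traits, and ``top_unmapped``
    frequencies count occurrences in the input list. Passing ``None`` for a
    matcher uses the built-in default; stages absent from
    ``cfg.stage_order`` are skipped entirely.
    """
    cfg = cfg or MapperConfig()
    if not hierarchy.pt_of:
        raise ConfigurationError("cannot map against an empty hierarchy")
    unknown = set(cfg.stage_order) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown cascade stages: {sorted(unknown)}")

    freq: dict[str, int] = {}
    first_seen: dict[str, str] = {}
    for t in traits:
        norm = normalize_term(t)
        freq[norm] = freq.get(norm, 0) + 1
        first_seen.setdefault(norm, t)
    ordered = sorted(first_seen)

    need_fuzzy = "fuzzy" in cfg.stage_order
    need_embed = "embedding" in cfg.stage_order
    if need_fuzzy and fuzzy is None:
        fuzzy = TokenSetFuzzyMatcher(hierarchy)
    if need_embed and embedder is None:
        embedder = CharTfidfEmbedder(hierarchy)

    mapped: list[MappedPhenotype] = []
    unmapped: list[str] = []
    stage_counts = {s: 0 for s in cfg.stage_order}
    for norm in ordered:
        hit: tuple[str, str, float] | None = None  # (stage, concept, similarity)
        for stage in cfg.stage_order:
            if stage == "exact":
                cid = _lexicon_match(norm, hierarchy)
                if cid is not None:
                    hit = (stage, cid, 1.0)
            elif stage == "fuzzy":
                cands = fuzzy.candidates(norm)
                if cands and cands[0][1] >= cfg.fuzzy_min_score:
                    hit = (stage, cands[0][0], cands[0][1])
            elif stage == "embedding":
                cands = embedder.candidates(norm)
                if cands and cands[0][1] >= cfg.embedding_threshold:
                    hit = (stage, cands[0][0], cands[0][1])
            if hit is not None:
                break
        if hit is None:
            unmapped.append(first_seen[norm])
            continue
        stage, cid, sim = hit
        stage_counts[stage] += 1
        mapped.append(
            MappedPhenotype(
                trait_text=first_seen[norm],
                concept_id=cid,
                pt_soc_pairs=hierarchy.pt_of[cid],
                stage=stage,
                similarity=sim,
            )
        )

    top_unmapped = sorted(
        ((first_seen[normalize_term(u)], freq[normalize_term(u)]) for u in unmapped),
        key=lambda kv: (-kv[1], kv[0]),
    )[:30]
    report = CoverageReport(
        per_stage_counts=stage_counts,
        n_total=len(ordered),
        n_unmapped=len(unmapped),
        top_unmapped=top_unmapped,
    )
    return mapped, unmapped, report


def per_source_unmapped(
    records: pd.DataFrame, unmapped: Iterable[str]
) -> dict[str, float]:
    """Fraction of each source's distinct traits that failed to map."""
    bad = {normalize_term(u) for u in unmapped}
    out: dict[str, float] = {}
    norm = records["trait_text"].map(normalize_term)
    for source, grp in norm.groupby(records["source_id"]):
        distinct = set(grp)
        out[str(source)] = len(distinct & bad) / len(distinct) if distinct else 0.0
    return out


def expand_links(
    records: pd.DataFrame, mapped: Sequence[MappedPhenotype]
) -> pd.DataFrame:
    """Fan harmonized associations out to one link per (gene, PT, SOC, source).

    Records whose trait did not map produce no links; a concept carrying
    several (PT, SOC) pairs produces one link per pair.
    """
    lookup = {normalize_term(m.trait_text): m for m in mapped}
    rows: list[tuple] = []
    seen: set[tuple] = set()
    for rec in records.itertuples(index=False):
        m = lookup.get(normalize_term(rec.trait_text))
        if m is None:
            continue
        for pt, soc in sorted(m.pt_soc_pairs):
            key = (rec.gene_symbol, pt, soc, rec.source_id)
            if key in seen:
                continue
            seen.add(key)
            rows.append(key + (rec.evidence_class, m.stage, m.similarity))
    return pd.DataFrame(rows, columns=LINK_COLUMNS).sort_values(
        ["gene_symbol", "pt_term", "soc_term", "source_id"], ignore_index=True
    )
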