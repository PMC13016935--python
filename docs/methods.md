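# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic test world does
and does not demonstrate.

## Evidence harmonization

Each source database arrives as a normalized TSV (column names remapped
via `sources.yaml`) and carries one of four filter policies:

| policy | rule | default parameters |
| --- | --- | --- |
| `gwas_like` | p-value present and ≤ threshold (inclusive), valid effect estimate | 5×10⁻⁸ |
| `clinvar_like` | sub-source annotation present and not excluded | excluded = {"NA"}; a missing value is treated as "NA", since the exclusion targets absent provenance |
| `disgenet_like` | association type ∈ genetic-evidence whitelist AND sub-source ∈ human-genetics whitelist | six mutation/variation classes; seven curated sub-sources |
| `passthrough` | no record-level filter | — |

After filtering, gene symbols are whitespace-trimmed and matched
case-sensitively (HGNC symbols are case-canonical), non-protein-coding
genes are dropped against the supplied gene universe, and records are
deduplicated on (gene, trait, source). Sources with no documented filter
(ontology annotation dumps, literature-mined associations, drug
indication tables) are pass-through; drug indications enter as
structured trait text with evidence class `pharmacological`.

## Phenotype mapping cascade

Traits are deduplicated on a normalized form (lowercase, punctuation →
spaces, whitespace collapsed) and tried against three stages in a fixed
order; the first stage producing an accepted candidate wins and only its
top-ranked candidate is kept.

1. **exact/partial** — dictionary lookup of the normalized trait in the
   synonym lexicon; failing that, substring containment between trait
   and synonym in either direction, longest synonym winning. Similarity
   is 1 by definition. The containment rule is a deliberately simple
   stand-in for thesaurus-style partial matching.
2. **fuzzy** — token-set-ratio similarity (order-insensitive; scores 1.0
   when one token set contains the other) over all synonyms, accepted at
   ≥ 0.85. The threshold is a package choice, set strict to keep
   stage-2 precision high; configurable.
3. **embedding** — cosine similarity of character-trigram TF-IDF vectors
   between the trait and every synonym, accepted at ≥ 0.70
   (inclusive). Inclusive acceptance is a documented choice.

Both stage-2 and stage-3 backends are injectable services behind a
one-method contract (`candidates(text) -> ranked (concept, similarity)`),
so heavier engines (terminology APIs, transformer embedders) can be
dropped in without touching the cascade. The built-ins are fully
deterministic; equal-similarity ties break to the lexicographically
smallest concept id, and embedding similarities are rounded to 12
decimals first so float jitter cannot reorder ties.

A concept associated with several (PT, SOC) pairs expands to all of
them rather than being forced to a single label, so one association
record can yield several gene–phenotype links.

The built-in matchers are not the point of the design — the cascade
shape, first-stage-wins attribution and the 0.7 acceptance boundary are.
Real-corpus coverage percentages depend entirely on the engines and
vocabularies plugged in and are not reproduced here.

## Scoring

Raw score = (Σ per-source deduplicated record counts) × ln(unique
sources + 1). Counts are *records after harmonization*, i.e. one per
distinct (gene, trait, source) — a database listing a gene under many
traits contributes each trait once, and repeated rows contribute
nothing. Then Z-normalization over the cohort (population σ: the cohort
is the full population of targets, not a sample), ln(z − min z + 1) to
damp the right tail, and min–max rescaling to [0, 10]. All four steps
are strictly monotone, so the scaled score preserves raw-score order.

Degenerate cohorts (single target, or all raw scores equal) cannot be
rescaled; every target is then assigned scaled = 10 and percentile = 0
with a logged warning. Rationale: uniform evidence should not silently
map to zero, and downstream percentile cutoffs then retain everything.

Percentile ranks for the safetyome cutoff use the strictly-below
convention: rank = 100 · #{strictly smaller} / N, ties sharing the rank
of their lowest member. Retention at the cutoff is inclusive
(percentile ≥ cutoff). Scoring is global across SOCs by default; a
per-SOC percentile mode re-ranks scaled scores within each organ's
linked genes and is the default for the cutoff sweep, mirroring
filtering "from each SOC".

## Panels

- SOC level: links to the configured non-organ SOCs are dropped first
  (their identity is a required config input — the package hard-codes no
  vocabulary), then genes below the percentile cutoff (default 50). The
  safetyome is the union of the panels.
- PT level: a gene joins a phenotype panel iff ≥ 2 distinct databases
  support that (gene, PT) pair, counted after multi-PT fan-out. Empty
  panels are not emitted.
- GMT export records level, per-gene source-count range and evidence
  classes in the description field.

## Prioritization

- **Tau index** τ = Σᵢ(1 − xᵢ/x_max)/(N−1) over tissues: 0 for uniform
  expression, 1 for single-tissue expression, undefined (missing, with a
  warning) for all-zero profiles. Scale-invariant by construction.
- **Conservation** per gene: median across mouse/rat/dog of (i) primary
  sequence identity and (ii) ortholog-call confidence (1 = high
  confidence, 0 = low/absent); each median percentile-ranked across
  genes (average-tie pandas pct-rank, in (0, 1]); score = mean of the
  two ranks. Ranking before averaging keeps the two metrics on a common
  scale; averaging raw values instead would let the identity percentage
  dominate the 0/1 confidence flag.
- **Core panel**: combined score = weighted mean (default unweighted) of
  the percentile ranks of scaled score, Tau and conservation; sort
  descending; ties break by scaled score then gene symbol, making ranks
  a deterministic permutation and top-k prefixes stable in k. Genes
  missing a metric are ranked on their available metrics and flagged
  rather than dropped. Top n = 500 by default.

## Orthogonal validation

Each panel is the query; each disease's direct-evidence gene set is a
term. p = P(X ≥ overlap) under the hypergeometric law on the annotated
universe (all genes with ≥ 1 direct-evidence disease annotation;
configurable). Adjustment is Benjamini–Hochberg at SOC level (the
convention of standard enrichment tooling) and Bonferroni at PT level,
both configurable; significance α = 0.05 on adjusted p. PT-level testing
is restricted to panels with ≥ 50 genes to avoid small-set instability.

A (panel, disease) pair is *matched* when the disease's independently
mapped label (via the same cascade) equals the panel id — exact label
equality; semantically close but distinct labels count as mismatches. A
disease whose mapped concept fans out to several labels matches any of
them. Match rate per panel = share of matched among significant results;
the mean is over panels with ≥ 1 significant result. The cutoff sweep
re-runs panel building and SOC-level testing at percentiles 10–90.

## Synthetic world

The generator emulates the complete input surface with opaque
vocabularies (SOC_01, PT_0042, GENE0001 — no real terminology strings):

- 27 SOCs (5 flagged non-organ) × 8 PTs each, one concept per PT, 10% of
  concepts carrying a second same-SOC PT; 3 synonyms per concept.
- 1,000 protein-coding genes plus a 5% non-coding margin. Each gene gets
  a primary SOC and draws 1–5 concepts mostly (70%) from it — pleiotropy
  is limited, most genes touch few organ systems. 60% of
  (gene, concept) assignments receive ≥ 2 supporting sources.
- Nine sources (seven genetic, two pharmacological) with the
  source-specific columns their policies need, plus ~10% junk rows per
  source constructed to fail that source's filter (above-threshold or
  missing p-values, invalid effects, "NA" provenance, non-genetic
  association types, non-coding genes), so zero-noise harmonization
  recovers the planted association list exactly.
- Diseases: per organ SOC, gene sets drawn from that SOC's
  best-evidenced *exclusive* genes (curated disease resources list
  established genes), labelled by a synonym of one of its concepts.
  Disease noise swaps genes for ones from a single contaminant SOC, so
  increasing noise first erodes significance and then produces
  wrong-panel enrichments — the match rate degrades monotonically.
- 50 planted core genes receive broad multi-source evidence,
  single-tissue expression and maximal identity/confidence, dominating
  all three prioritization metrics.
- Trait noise applies adjacent-character swaps inside the first tokens
  (defeating both exact lookup and substring containment) plus optional
  suffix tokens, so the fuzzy and embedding stages are genuinely
  exercised. Default rates: trait noise 0.1, association dropout 0.05,
  disease noise 0.1 — enough to engage every recovery path while keeping
  the planted structure dominant.

Everything derives from one `numpy` Generator seed; identical seeds
yield byte-identical files.

What passing tests on this world show: the pipeline's bookkeeping,
thresholds, ranking and statistics behave exactly as specified, and
recovery degrades monotonically with injected noise. What they do not
show: performance on real vocabularies (synonymy is far messier than
the generated lexicon), real trait corpora (composite GWAS trait
descriptions often have no ontology counterpart), or real disease–gene
resources (shared upstream curation between evidence sources and the
validation resource inflates agreement). Reported coverage and match
percentages on real data depend on those inputs and on the matcher
engines plugged into the cascade.

## Problem sizes and runtime

The test suite uses compact worlds (≈250 genes, 9 SOCs) for integration
tests and the 400–2,000-gene range where a contract is about scale
(exact core-panel size, half-retention at the 50th percentile); the
end-to-end zero-noise recovery check runs in seconds on one CPU. The
demo world in the README uses the 1,000-gene defaults.

## Known limitations

- The substring-containment partial match can shortcut traits that a
  semantic matcher would route to a better concept; it is intentionally
  conservative and stage-attributed so downstream analysis can filter
  by stage.
- The conservation score treats identity and ortholog confidence as
  exchangeable after ranking; with more species or continuous confidence
  measures a weighted scheme may be preferable (weights are exposed for
  the core-panel combination only).
- Match-rate validation requires exact label equality; near-synonym
  labels (different granularity of the same condition) count as
  mismatches, which understates agreement on real vocabularies.
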