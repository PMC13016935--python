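# safetyome

Construction, prioritization and orthogonal testing of off-target safety
panels from harmonized human-genetics and pharmacology evidence.

## The problem

Drug candidates are routinely counter-screened against panels of
*off-targets* — proteins they were never designed to touch but whose
perturbation has phenotypic consequences. Choosing which proteins belong
on such a panel is traditionally manual and poorly translatable. Human
genetics (Mendelian disease genes, genome-wide association hits) and
indication-based pharmacology both establish direct target→phenotype
links, and targets backed by that evidence are far more likely to be
phenotypically consequential when hit.

This package implements that idea as a reproducible pipeline:

1. **harmonize** — load gene–trait association tables from multiple
   evidence databases (seven genetic, two pharmacological), apply
   source-specific filters (genome-wide significance p ≤ 5×10⁻⁸ with a
   valid effect estimate for GWAS-style sources; removal of records with
   missing provenance for ClinVar-style sources; genetic
   association-type and sub-source whitelists for DisGeNET-style
   sources), restrict to protein-coding genes and deduplicate.
2. **phenomap** — map free-text traits onto a two-level safety ontology
   (system organ class, SOC, at the organ level; preferred term, PT, at
   the phenotype level) through a three-stage cascade: exact/partial
   lexicon lookup, then fuzzy string matching, then character-trigram
   TF-IDF embedding similarity with inclusive acceptance at 0.7. A
   concept carrying several (PT, SOC) pairs fans out to all of them.
3. **scoring** — condense each target's evidence into a 0–10 score
   (see below) and a percentile rank.
4. **panels** — assemble the organ-level *safetyome* (non-organ SOCs
   excluded, score percentile ≥ 50 retained) and PT-level specialized
   panels (gene–PT pairs supported by ≥ 2 databases), exported as GMT
   gene sets.
5. **prioritize** — rank safetyome targets by the Tau
   tissue-specificity index, a cross-species conservation score and the
   scaled evidence score; the top 500 form the core screening panel.
6. **validate** — test every panel against an independent disease–gene
   table by one-sided hypergeometric over-representation, adjust for
   multiplicity (Benjamini–Hochberg at SOC level, Bonferroni at PT
   level, PT panels < 50 genes excluded), and report *match rates*: the
   percentage of a panel's significantly enriched diseases whose
   independently mapped label equals the panel's own. A cutoff sweep
   from the 10th to the 90th percentile shows how panel size trades off
   against match rate.

## The score

For a target with per-source deduplicated record counts
$c_1, \dots, c_n$ of which $u$ are non-zero:

$$\text{raw} = \Big(\sum_i c_i\Big)\,\ln(u + 1)$$

$$z = \frac{\text{raw} - \mu}{\sigma}, \qquad
\ell = \ln\big(z - \min z + 1\big), \qquad
\text{scaled} = 10\,\frac{\ell - \min \ell}{\max \ell - \min \ell}$$

with $\mu, \sigma$ the cohort mean and (population) standard deviation.
The unique-source multiplier rewards independent corroboration while
preventing one prolific database from dominating; the log transform
damps extreme values; min–max rescaling puts every cohort on a common
0–10 scale. Percentile ranks of the scaled score (ties share the rank of
the lowest member) drive the safetyome cutoff.

## Worked example

No external data is required: the `simulate` subcommand generates a full
synthetic input world (hierarchy, nine source tables with filterable
junk, disease–gene table, expression matrix, orthology table) with
planted ground truth.

```sh
safetyome simulate --out world --seed 7 --n-genes 1000
safetyome run-all --config run.yaml      # points input_dir at world/
```

prints (run configuration: the five non-organ SOCs excluded, cutoff 50,
defaults elsewhere):

```
n_harmonized_records: 8433
n_links: 7325
n_scored_genes: 913
n_safetyome_genes: 385
n_soc_panels: 22
n_pt_panels: 214
n_core_panel: 385
mean_soc_match_rate_pct: 100.0
```

8,433 filtered, deduplicated associations over 913 protein-coding genes
survive harmonization; mapping and fan-out yield 7,325 gene–PT–SOC–source
links; the 50th-percentile cutoff retains a 385-gene safetyome across the
22 organ SOCs, and every significantly enriched disease lands in its own
organ panel (100% match rate — by construction at this noise level). The
emitted `cutoff_sweep.tsv` shows the size/match-rate trade-off, e.g.
611 targets at the 10th percentile (98.9% match) shrinking to 25 at the
90th.

Query the results from either side:

```
$ safetyome query-gene --results out GENE0986
GENE0986: scaled score 10.000 (percentile 99.9)
  SOC_04: src_clinvar,src_disgenet,src_drugbank,src_gwas,...
  SOC_09: src_clinvar,src_disgenet,src_gwas,src_hpo,...

$ safetyome query-pt --results out PT_0001
  GENE0179   9.815   src_clinvar,src_ttd
  GENE0463   9.721   src_disgenet,src_drugbank,src_litmine
  ...
```

Real inputs use the same TSV schemas (one table per source, a
`sources.yaml` column map, a concept/synonym/PT/SOC hierarchy table, a
two-column gene universe, a disease–gene table with direct-evidence
flags, a gene × tissue expression matrix and a long-form orthology
table); see `docs/methods.md`.

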