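# exotriage

Rule-based clinical triage of annotated whole-exome variant tables, built for
small, well-phenotyped rare-disorder cohorts (the packaged defaults target a
pediatric motor speech disorder cohort of 10 participants).

The pipeline takes one row per called variant per sample — with consequence
type, per-database allele frequencies, five in-silico effect-predictor calls,
zygosity and read support — and:

1. **Prioritizes** variants with four rules and full filter provenance:
   * allele frequency — deprioritize when the maximum frequency across the
     queried databases (dbSNP 137, EVS/ESP6500, 1000 Genomes, in-house)
     strictly exceeds 0.3%; a variant absent everywhere is novel and passes;
     frequency failures in phenotype-associated genes (or with prior variant
     evidence, or in cohort-level genes of interest) are rescued for review;
   * impact class — known-functional (class 1); premature stop, start loss,
     canonical splice, stop read-through, frameshift indel (class 2);
     near-splice (≤10 bases), in-frame indel, or nonsynonymous with a
     damaging predictor consensus ≥3/5 (class 3); everything else drops out;
   * read support — deprioritize calls supported by fewer than 10% of reads;
   * known-neutral — exclude variants previously confirmed neutral.
   Zygosity is recorded and reported, never filtered.
2. **Assigns report categories** per prioritized variant using a curated
   gene-knowledge table (gene → association tier): `LIKELY_PATHOGENIC`
   (novel + unanimous damaging + causally associated gene), `VUS`,
   `VUS_IN_GUS` (damaging change in a gene of uncertain significance), and
   builds the cohort report: reportable participants, shared variants,
   multi-gene ("two-hit") candidates.
3. **Summarizes class counts** per sample (genes and variants per rare impact
   subcategory) and **phenotype grids** (missing-data-adjusted rates), plus
   cost-per-diagnosis arithmetic.
4. **Generates synthetic exome-scale cohorts** (default 120,000 variants per
   sample) with planted ground truth, so that prioritization and category
   assignment can be verified exactly against an independent encoding of the
   same rules.

## CLI

```sh
# triage a cohort: prioritized.tsv, class_summary.tsv, cohort_report.json
exotriage triage --variants cohort.tsv --participants 3,5 --cohort-size 10 --out out/

# thresholds are configurable (YAML --config or flags)
exotriage triage --variants cohort.tsv --frequency-threshold 0.003 \
    --min-read-support 10 --genes my_genes.yaml --out out/

# generate a synthetic cohort with a truth table per sample
exotriage simulate --samples 10 --reportable-fraction 0.8 --seed 7 --out sim/

# missing-data-adjusted phenotype rates (packaged 10-participant grid by default)
exotriage phenotype
```

Variant tables use a documented TSV dialect (`exotriage.io.VARIANT_COLUMNS`);
coordinates are 1-based inclusive, absent allele frequencies are written `NA`
and never coerced to 0, and read support is a 0–100 percentage. An optional
VCF 4.x dialect (`--dialect vcf`) maps INFO keys onto the same model. Gene
knowledge is YAML or TSV (`gene`, `tier`, `phenotype_note`, `prior_variants`);
the packaged default table covers FOXP1/FOXP2/CNTNAP2/ATP13A4 (causal tier),
KIAA0319 (overlapping phenotype) and SETX/CNTNAP1 (uncertain significance).

## Packaged fixtures

* `exotriage.io.load_cohort_fixture()` — a 10-participant cohort with 12
  prioritized variant records in 6 genes on 5 chromosomes (2 participants
  without findings), with expected report categories per record.
* `exotriage.io.load_phenotype_fixture()` — the matching 10-participant
  phenotype grid (`+` / blank / `ND` cell codes; blank encodes negative).

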