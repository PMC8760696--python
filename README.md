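# mpnpanel

Post-variant-calling analysis for a 22-gene targeted amplicon myeloid panel.
The package covers everything downstream of primary variant calling for an
MPN (myeloproliferative neoplasm) screening workflow:

- **`io_formats`** — strict readers/writers for the formats the pipeline
  touches (VCF v4.2 call sets, BED4 amplicon manifests, TSV annotation /
  coverage / truth-set tables), with one internal coordinate convention
  (1-based inclusive, `chrN` naming) and deterministic output.
- **`caller_merge`** — allele-context indel normalization and reconciliation
  of the two complementary callers (a small-variant caller that sees
  everything except large duplications, and a structural caller that sees
  indels and large events but not SNVs) into one call set per sample.
- **`triage`** — the somatic variant filtering/prioritization cascade:
  exonic-only region filter → population-MAF filter (≥ 1% in any of 1000
  Genomes/ExAC/ESP6500/gnomAD excludes) → artifact filter (VAF < 5%, or
  recurrence in a majority of cohort samples without database pathogenicity
  evidence) → pathogenic rescue of 1–5% VAF calls with ClinVar P/LP or
  COSMIC pathogenicity support; plus novelty classification against
  dbSNP/ClinVar/COSMIC and a ≥ 15% Sanger-confirmability flag. Every
  (sample, variant) occurrence gets an audited decision.
- **`panel_validation`** — scoring of replicate runs against reference
  standards: detection matrices, sensitivity/specificity/PPV (with an
  explicit cross-standard negative-site convention for true negatives),
  intra-/inter-run concordance (Jaccard by default), and limit of detection
  over expected-VAF tiers.
- **`coverage_qc`** — per-amplicon mean-depth flags (< 1000x warn, < 100x
  critical), on-target rate, 30 bp GC-window profiling and the GC-vs-depth
  dropout association (Spearman).
- **`synthetic_data`** — seeded generators for every input: a 219-amplicon
  panel with a high-GC dropout analogue, four reference standards (26
  unique truth variants), logistic GC-dropout coverage, binomial read
  support with caller detection floors, and a 10-sample MPN-like cohort
  (7 hotspot-SNV drivers, 3 private frameshift drivers) with full ground
  truth labels.
- **`cli` / `report`** — a `mpnpanel` command-line tool and deterministic
  markdown/JSON reports.

A packaged fixture (`mpnpanel.fixtures`) encodes the published 10-sample
clinical cohort — demographics, all 28 variant occurrences with printed
VAFs and their database annotations — and is used by the regression and
acceptance tests.

## CLI

```sh
mpnpanel simulate --seed 7 --out-dir sim/                # synthetic input tree
mpnpanel merge --small S01.small.vcf --structural S01.structural.vcf \
    --out S01.merged.vcf --log-out S01.merge_log.tsv
mpnpanel triage --calls S01.merged.vcf --calls S02.merged.vcf \
    --annotations annotations.tsv --out-dir triage/
mpnpanel validate --truth truth_sets.tsv \
    --replicate SeraseqMyeloid:rep1:run1:sera_r1.vcf --out validation.json
mpnpanel coverage-qc --coverage coverage.tsv --fasta panel.fa --out-dir qc/
mpnpanel demographics --table1 table1.tsv
mpnpanel report --decisions triage/decisions.tsv \
    --triage-summary triage/summary.json --out-dir report/
```

Exit codes: 0 success, 1 validation/domain error, 2 I/O or usage error.
All thresholds live in a TOML config (`--config`); defaults are the
validated workflow's values (5% retention VAF, 1% MAF cutoff, 15% Sanger
flag, 100x/1000x coverage bands, 25-base large-event cutoff, 30 bp GC
windows).

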