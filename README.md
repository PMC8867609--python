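# methaplo

Read-level CpG methylation statistics and case–control association for
targeted bisulfite amplicon panels, plus a two-cohort array-style screen
for differentially methylated CpGs (DMCs) and a synthetic cohort
generator so the whole pipeline is testable offline.

## What it does

- **io_formats** — BED region panels (0-based on disk, 1-based in
  memory), read-level methylation pattern TSVs (alphabet `M`/`U`/`N`),
  beta matrices with probe annotations, sample metadata. All round-trip
  losslessly.
- **simulate** — synthetic read cohorts (first-order Markov chain across
  adjacent CpGs with configurable marginals and lag-1 correlation,
  between-subject logit variance, case/control logit shifts, Poisson
  depth, incomplete bisulfite conversion, missing calls) and paired
  array-style beta cohorts with spiked case/control shifts.
- **qc** — sample conversion-rate filter (< 0.95 removed), per
  sample-region depth filter (< 100× removed), pooled site-missingness
  filter (> 30% removed), replicate concordance.
- **regionstats** — per-CpG betas, weighted methylation level
  (WML = ΣC/Σ(C+T)), haplotype tables, methylation haplotype burden
  (MHB = Σ f·P), Spearman comethylation matrices.
- **screening** — probe blacklist + missingness filters, probe-wise kNN
  imputation, per-probe t-test with the conjunctive p < 0.05 and
  |Δβ| > 0.015 rule, two-cohort intersection.
- **association** — Youden-index cutoffs, hypo/hyper dichotomization,
  2×2 odds ratios with Woolf 95% CIs, Pearson χ², logistic regression
  (IRLS) with covariate adjustment, Bonferroni correction.
- **pipeline** — one-YAML orchestration with a JSON manifest;
  deterministic under a fixed seed.

## CLI

```bash
methaplo run --config pipeline.yaml --out-dir run1 --seed 1
methaplo simulate --config pipeline.yaml --out-dir sim
methaplo validate --regions sim/regions.bed --reads sim/reads.tsv --meta sim/meta.tsv
methaplo qc --reads sim/reads.tsv --regions sim/regions.bed --meta sim/meta.tsv --out qc.tsv
methaplo region-stats --reads sim/reads.tsv --regions sim/regions.bed --out-dir stats
methaplo screen --beta1 sim/beta_cohort1.tsv --beta2 sim/beta_cohort2.tsv --out dmcs.tsv
methaplo associate --measures measures.tsv --meta sim/meta.tsv \
    --adjust age,family_history_bc,family_history_other --out assoc.tsv
methaplo table2x2 127 106 248 92
```

Every YAML key has a default; any subset may be overridden. See
`methaplo <cmd> --help` for flags.

## Conventions

- Tab-separated UTF-8 files, `NA` for missing, `#`-prefixed headers.
- Thresholds are strict exactly as documented (e.g. conversion `< 0.95`
  removed, site missingness `> 0.30` removed, value `>= cutoff` → hyper).
- All randomness flows from a single master seed; subject-level PRNG
  streams make the read simulator reproducible under any scheduling.
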