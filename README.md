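# aisle

Allelic-imbalance discovery and super-enhancer annotation for case/control
functional-genomics data: chromatin-accessibility and RNA allelic read
counts, chromHMM 15-state segmentations, window tag tracks, RRBS CpG
methylation and case/control genotypes.

The package implements a two-stage workflow:

* **Stage I (discovery)** — variant QC cascade (mapping quality < 20,
  ≥3-SNP clusters within 10 bp, quality-by-depth < 2, strand bias > 50,
  genotype quality < 15, allelic depth < 8), heterozygote extraction with
  a ≥3-per-group recurrence rule, per-SNP allelic-ratio regression on
  disease status, Fisher combination across datasets and reciprocal
  validation (per-dataset p < 0.05, combined p < 0.01), stratified by cell
  state.
* **Stage II (annotation)** — super-enhancer calling as maximal abutting
  runs of chromHMM states 6–7 spanning ≥3 kb, cross-epigenome specificity
  profiles, 50-bp-window tag-per-million quantification with ECDF/Q3
  summaries and developmental-stage trend regressions, length-matched
  background sampling with an add-one empirical p, per-window CpG
  methylation (site-mean aggregation, missing ≠ 0) with stage trends and
  TPM–methylation correlation, and genetic association (log-additive
  logistic with covariates, conditional adjustment for index SNPs, two-SNP
  EM haplotype analysis, LD r²).

A synthetic-data module generates every input format with the statistical
structure the analyses assume (beta-binomial allelic counts with planted
group-specific fractions and direction flips, planted enhancer runs,
stage-trending window and methylation tracks, genotypes with a log-additive
effect and an LD partner SNP), so the full pipeline is testable offline.

## CLI

```bash
aisle simulate --config cfg.yaml   # write synthetic inputs to <out_dir>/inputs
aisle discover --config cfg.yaml   # stage I: QC + AI tests + validation
aisle annotate --config cfg.yaml   # stage II: SE / TPM / methylation / association
aisle all      --config cfg.yaml
aisle se-call segmentation.bed --states 6,7 --min-len 3000
aisle quantify counts.tsv samples.tsv --region chrS:0-7000 --window 50
```

Minimal config (all thresholds default to the published values):

```yaml
seed: 7
out_dir: out
simulate:
  n_snps: 20
  planted_ai: [[0, 0.65, 0.50, null]]   # snp index, case frac, control frac, cell state
  assoc_effect: -0.262                  # log(0.77)
```

Outputs are TSV/JSON; every file carries the config hash and reruns are
byte-identical under a fixed seed.

## Library use

```python
from aisle.allelic import ai_test, fisher_combine, reciprocal_validate
from aisle.superenhancer import parse_segmentation, call_superenhancers
from aisle.association import additive_logistic, em_haplotypes_2snp, ld_r2
```

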