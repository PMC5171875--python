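# tsmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection, allele harmonization, and causal-effect estimation
with inverse-variance-weighted (IVW), MR-Egger and weighted-median
estimators, plus a summary-level simulator with known ground truth and a
configuration-driven analysis grid runner.

## What it does

- **`tsmr.summary_io`** — read/validate delimited GWAS summary tables with a
  user-supplied column map; genome-wide-significance filtering (default
  p < 5e-8); greedy LD pruning at r² ≥ 0.8 keeping the smaller-p / larger-effect
  SNP (LD is supplied as an input table, never looked up live); harmonization
  of exposure and outcome betas onto a common effect allele (palindromic SNPs
  are harmonized by letters with a warning); pleiotropy-tag annotation and
  exclusion. Every removal is logged — nothing is silently dropped.
- **`tsmr.estimators`** — per-SNP Wald ratios with Fieller-theorem confidence
  limits (bounded / unbounded / exclusive cases); fixed-effect IVW with
  first-order weights; MR-Egger regression (intercept = average directional
  pleiotropic effect, two-sided normal p-value); weighted median with a
  parametric-bootstrap SE; odds-ratio conversion for binary outcomes.
- **`tsmr.sensitivity`** — the with/without-pleiotropic-SNPs battery and the
  weight-share rule: weighted median when every SNP carries < 50% of the IVW
  weight, MR-Egger when a single SNP carries more (ties go to MR-Egger).
  Egger intercepts are reported for every set with ≥ 3 SNPs.
- **`tsmr.simulate`** — summary-level two-sample simulation under
  configurable pleiotropy regimes (`none`, `balanced`, `directional_inside`,
  `directional_inside_violated`), a replicate harness for bias/coverage
  studies, and a deterministic liver-enzyme demo fixture (4 ALT / 14 ALP /
  26 GGT instruments with a pleiotropy-tag table).
- **`tsmr.pipeline` / `mr` CLI** — YAML-configured exposure × outcome grid
  producing a report-shaped TSV, a full-precision JSON bundle, per-pair
  instrument logs and a reproducibility run log.

## CLI

```sh
# write the demo fixture (tables, tags, ready-to-run config)
mr fixture --out demo/

# run the full analysis grid
mr run --config demo/config.yaml

# replicate simulation study
mr simulate --truth truth.yaml --reps 500 --seed 1
```

`truth.yaml` holds `SimulationTruth` fields, e.g.:

```yaml
beta_causal: 0.4
n_snps: 50
pleiotropy_regime: directional_inside
mu_alpha: 0.05
sigma_alpha: 0.01
invalid_fraction: 1.0
```

## Notes on conventions

- Exposure betas are expected in proportional-change units (1.0 = 100%
  change in concentration); a per-table `rescale` factor in the config
  accommodates per-SD or per-percent sources.
- 95% CIs use z = 1.96 throughout; the Fieller interval is attached to each
  Wald ratio as a diagnostic while IVW pooling uses first-order SEs.
- MR-Egger SEs default to fixed-effect normal theory
  (`egger_residual_variance: none`); `multiplicative` inflates by the
  residual SD when it exceeds 1.
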