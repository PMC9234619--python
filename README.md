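# gsel — genomic selection toolkit

A tested, reusable pipeline for genomic selection studies on aquaculture-style
random-mating populations:

- **`gsel.simdata`** — synthetic datasets: founder haplotypes with tunable
  allele frequencies and AR(1)-copula linkage disequilibrium, one generation
  of random mating with recombination, an additive trait with batch fixed
  effects, heritability targeting and a recording ceiling (censored
  heat-challenge attachment durations), independent genotype missingness, and
  attachment-curve summaries.
- **`gsel.qc`** — genotype quality control (MAF > 0.05, SNP call rate > 0.95,
  individual call rate > 0.8 by default; individuals → SNP call rate → MAF
  order) and naive mean / Hardy-Weinberg-sample imputation.
- **`gsel.structure`** — VanRaden (method 1) genomic relationship matrix and
  GRM-based PCA with Tracy–Widom significance screening.
- **`gsel.gwas`** — EMMAX-style mixed-linear-model association scan
  (exact null REML via eigen-rotation, per-marker Wald tests), Bonferroni +
  suggestive thresholds, per-SNP variance explained, significance
  classification, GFF3 candidate-gene proximity annotation, Manhattan/QQ
  table export.
- **`gsel.predict`** — GBLUP with exact profile-REML variance components and
  mixed-model-equation GEBVs, and a from-scratch BayesB spike-and-slab Gibbs
  sampler (numba-compiled core, bit-reproducible under a fixed seed);
  heritability h² = σg² / (σg² + σe²).
- **`gsel.evaluate`** — k-fold × repeats cross-validation, accuracy (Pearson
  r between phenotype and GEBV), bias (regression of phenotype on GEBV), and
  the GWAS-ranked vs random SNP-panel experiment grid with leakage-safe
  fold-internal ranking.
- **`gsel.pipeline` / `gsel.cli`** — config-driven end-to-end orchestration
  with per-stage derived seeds and a hashed provenance manifest.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
checks on printed study values plus statistical pipeline properties); the
rest are per-module unit/property tests. The statistical tests use scaled
simulation sizes and fixed seeds; the full suite runs in a few minutes on
one CPU.

## CLI

```bash
# full pipeline on a simulated population (writes manifest + all tables)
gsel run-all --config config.yaml --seed 1 --out runs/demo

# individual stages
gsel simulate --config config.yaml
gsel qc --config config.yaml
gsel structure --config config.yaml
```

A minimal config:

```yaml
simulate:
  n_founders: 400
  n_offspring: 1120
  m: 5000
  n_chrom: 18
  n_qtl: 200
  h2_target: 0.40
  missing_rate: 0.008
predict:
  models: [GBLUP, BayesB]
  chain_profile: fast     # "paper" = 100,000 iterations / 3,000 burn-in
cv:
  k: 5
  repeats: 10
  panels:
    - {mode: top_gwas, size: 500}
    - {mode: random, size: 500}
    - {mode: all}
seed: 1
out_dir: runs/demo
```

Outputs include a Table-1-style association table (`gwas_results.tsv`),
variance components + heritability per method (`variance_components.csv`),
the CV accuracy/bias grid (`cv_cells.csv`, `cv_aggregate.csv`), GRM and PC
scores, QC report, and a `manifest.json` with SHA-256 hashes of every
artifact (identical config ⇒ identical hashes).

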