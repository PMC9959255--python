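# dcx

A toolkit for two-group airway-epithelium microarray analysis, built
around differential co-expression. It covers the full desk pipeline:

- **`dcx.simulate`** — synthetic data with ground truth: two-group
  expression matrices with planted log2 effects and correlated gene
  modules (single-latent-factor model, exact target correlations in
  expectation), clinical/biomarker tables, and 16-bit array-scan images
  with positioning markers and known spot geometry.
- **`dcx.gridding`** — scan gridding: maximally-stable-extremal-regions
  (MSER) marker detection on a max-tree of the image, least-squares
  affine grid fitting with exhaustive marker-anchor assignment, and
  disk/annulus spot quantification.
- **`dcx.preprocess`** — background correction (floor rule), quantile
  normalization, and coefficient-of-variation filtering (default band
  0.3–10 on the intensity scale).
- **`dcx.diffexpr`** — gene-wise covariate-adjusted differential
  expression (OLS with a group indicator: the ANCOVA formulation),
  Benjamini–Hochberg adjustment, and an expected-false-positive
  sample-size calculator.
- **`dcx.coexpress`** — differential co-expression: hierarchical
  clustering on 1 − r distance in one condition, one-sample t over
  within-group pairwise correlations, gene-resampling null p-values,
  the EA/NEA decision rule (non-random in EA, random in NEA), and
  ranking by mean pairwise correlation difference.
- **`dcx.network`** — typed graph assembly, exact betweenness
  centrality, topological-attack robustness curves,
  centrality-vs-literature "understudied" ranking, and hypergeometric
  over-representation analysis against GMT gene-set libraries.
- **`dcx.clinical`** — Shapiro–Wilk-gated group comparisons
  (t / Mann–Whitney / chi-squared), correlations, the logistic-regression
  optimal biomarker cut-off, and harmonic-mean thickness summaries.
- **`dcx.io` / `dcx.pipeline` / `dcx.cli`** — TSV/GMT/SIF/JSON/YAML
  readers and writers and the orchestrated end-to-end pipeline with a
  reproducibility manifest.

## CLI

All functionality is exposed through the `dcx` command:

```sh
dcx simulate --n-genes 1000 --module 30:0.7:0.0 --seed 1 --out-dir demo/
dcx preprocess --matrix demo/expression_raw.tsv --annotation demo/samples.tsv \
    --out demo/processed.tsv --report demo/cv_report.tsv
dcx de --matrix demo/processed.tsv --annotation demo/samples.tsv \
    --covariates age,sex,bmi,ocs --out demo/de.tsv
dcx coexpress --matrix demo/processed.tsv --annotation demo/samples.tsv \
    --alpha 0.05 --resamples 1000 --seed 1 --out demo/groups.tsv
dcx grid --image scan.tif --layout layout.yaml --out signals.tsv
dcx network --edges net.tsv --attack betweenness --recompute --out-dir demo/
dcx clinstats --table demo/clinical_table.tsv --out demo/clinical_summary.tsv
dcx samplesize --n-genes 14823 --fold 2 --sigma 0.7 --power 0.8 --expected-fp 4
dcx run --seed 1 --out-dir demo-run/       # full synthetic demo pipeline
```

## Layout

```
src/dcx/         package source (one module per pipeline stage)
tests/           pytest suite; test_acceptance.py holds the acceptance criteria
scripts/         acceptance report generator
```
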