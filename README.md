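# dige-biomarker

A tested re-implementation of a 2D-DIGE tumor/benign biomarker analysis
pipeline, driven by a synthetic study generator (the original gel data are
not publicly deposited). The package covers:

- **`syndata`** — synthetic DIGE studies: 24 tumor + 24 benign samples on
  shared gels with Cy3/Cy5 dye swap and a pooled Cy2 internal standard;
  ~79 proteins expanded to ~110–125 spots; class signal carried by three
  latent factors plus sparse direct fold changes; a tight ~10-sample tumor
  subgroup; gel/dye nuisance effects and missing spots. Also ships the
  packaged clinical-metadata table (24 patients) and the 26-entry
  tumor-group differential-expression table.
- **`dige_io`** — spot-volume TSV I/O, internal-standard (Cy2) ratio
  normalization, failed-sample exclusion, presence filtering, median
  imputation, log2 matrix assembly, and clinical-table summaries.
- **`diffexp`** — pooled-variance two-sided t-tests and fold changes with
  the ≥1.5-fold / p<0.05 filter (no multiple-testing correction).
- **`cluster_partition`** — UPGMA (average-linkage, Euclidean) sample
  clustering with Newick export; single-feature threshold partition scored
  by a two-sided Fisher exact test (probability-mass rule).
- **`pca_split`** — two-step outlier-robust PCA (robust z > 3.5 on component
  scores, one refit); exact projection/residual split of every feature
  profile into the first-3-PC subspace (S3) and its complement (CS3);
  component-wise t-tests.
- **`panel_classifier`** — 3-PC logistic regression (Newton/IRLS with an L2
  separation fallback), leave-one-out cross-validation with the PCA refit
  inside every fold, tumor-group splitting on the linear predictor,
  per-PC correlation ranking, and the random-panel averaging experiment
  (median LOOCV accuracy and odds ratio vs. panel size 1–25).

## CLI

All stages write TSV/JSON outputs plus diagnostic figures into `--outdir`:

```sh
dige-biomarker --outdir out --seed 1 all            # full pipeline
dige-biomarker --outdir out --seed 1 simulate       # or stage by stage:
dige-biomarker --outdir out normalize
dige-biomarker --outdir out diffexp
dige-biomarker --outdir out cluster
dige-biomarker --outdir out pca
dige-biomarker --outdir out classify
dige-biomarker --outdir out panel
```

Generator parameters and analysis thresholds can be overridden with a YAML
file passed via `--config`:

```yaml
synthetic:
  n_proteins: 79
  noise_sd: 0.3
analysis:
  min_presence: 0.8
  panel_reps: 100
```

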