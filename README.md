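# gliomics

A radiogenomic analysis pipeline, exercisable end to end on a fully
synthetic cohort: 3D radiomics texture features from transformed MR-like
volumes, repeated-Lasso stability feature selection, class-weighted
logistic prediction with repeated stratified-split evaluation and averaged
ROC/PR curves, plus genomic status calling and association/survival
statistics.

## Modules

| Module | Role |
| --- | --- |
| `gliomics.synthcohort` | Synthetic cohort generator: genomic/clinical tables, proportional-hazards survival, and 4-sequence co-registered volumes with label-dependent ROI texture |
| `gliomics.genomics` | Mutation calls from variant tables, arm-level deletion and 1p/19q codeletion from copy-number segments, WHO-2016-style reclassification, mutation-frequency screen |
| `gliomics.assoc_stats` | Pearson chi-square (uncorrected), Mann-Whitney U (exact enumeration for small samples), Kaplan-Meier with median survival, log-rank, multivariate Cox (Efron ties, via lifelines) |
| `gliomics.imgproc` | White-stripe intensity normalization, fixed-bin-width discretization, and the transform bank: 3D wavelet sub-bands (LLL...HHH, hand-rolled Coiflet-1), square/square-root/logarithm/exponential, gradient magnitude, 2D/3D local binary patterns |
| `gliomics.texture` | First-order statistics and GLCM / GLSZM / GLDM / NGTDM texture families, feature-name codec, cohort feature-table extraction |
| `gliomics.stability` | Repeated cross-validated Lasso selection with selection-count ranking and top-round(sqrt(n)) truncation; clustered feature-correlation map |
| `gliomics.evaluate` | Class-weighted logistic model, 1000-repetition stratified 80/20 evaluation, vertical curve averaging, corner-distance cutoffs, U-test + top-third highlighting, exemplar selection |
| `gliomics.pipeline` / `gliomics.cli` | Orchestration, cohort screening, hashed artifact manifests, CLI |

## CLI

```bash
gliomics init-config config.yaml       # write the default profile
gliomics run-all --seed 1 --out run1   # full synthetic pipeline
gliomics simulate --seed 1 --out sim --write-images
gliomics screen images.json genomic.json
gliomics genomics variants.tsv segments.tsv --out status.csv
```

`run-all` writes cohort tables, genomic status calls, association results,
the feature table, the selection ranking, evaluation metrics/curves, and
exemplar descriptors, plus `manifest.json` with a SHA-256 per artifact —
re-running with the same seed reproduces every hash.

## Notes on conventions

- Degenerate-case conventions are fixed and documented in
  `gliomics.texture`: GLCM Correlation = 1 at zero variance, NGTDM
  Busyness/Strength = 0 on vanishing denominators, first-order Kurtosis
  (Pearson, non-excess) sentinel 0 on constant ROIs.
- The wavelet default is the stationary (undecimated) variant so every
  sub-band shares the input lattice and ROI mask; the decimated orthogonal
  variant (used by the energy-conservation tests) is available via
  `wavelet_subbands(..., stationary=False)`.
- The 2x2 chi-square applies no continuity correction by default; Yates
  correction is available behind a flag.
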