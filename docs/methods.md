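# Methods

`stagemark` re-implements a stage-informed biomarker-discovery and
diagnosis workflow for bulk transcriptomics: from a stage-labeled
expression cohort it derives a minimal marker panel and trains an
unsupervised cancer-vs-normal classifier in the panel's principal-component
space. This note records the models, the numerical choices, and the
limits of what the synthetic cohorts can demonstrate.

## Pipeline

1. **Low-variation filter.** Genes with sample standard deviation
   strictly below 1.0 on the input (normalized-count) scale are removed.
   The sd is computed before any transformation; the rule keeps a gene
   whose sd is exactly at the threshold.
2. **voom transform.** Counts become log2 counts-per-million,
   `log2((y + 0.5) / (libsize + 1) * 1e6)` with library size the column
   sum. A lowess trend (span 0.5) of sqrt residual standard deviation
   against mean log2 count — residuals from an intercept-only per-gene
   model — yields per-observation precision weights
   `1 / trend(fitted log2 count)^4`, clamped to the trend's fitted range.
   Matrices with fewer than ten genes fall back to a flat trend, since a
   lowess fit is meaningless there.
3. **Stratified split.** 80:20 by diagnosis class; per-class train counts
   are `round(ratio * class size)` with round-half-away-from-zero. The
   whole filtered matrix is voom-transformed once and the models are then
   fitted on the training columns; held-out samples reuse the same
   per-sample log-CPM formula at evaluation time.
4. **Stage models.** Per gene, two weighted least-squares fits on voom
   log-CPM with voom weights:
   * stage-indicator model `Y = α + β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄`, where
     `x_s` indicates pathologic stage `s`; α is the control baseline and
     each β_s a log2 fold-change versus controls;
   * ordinal model `Y = aX + b` with numeric stage `X ∈ {0,…,4}`
     (0 = control).
   Residual variances are moderated across genes by moment-matching the
   scaled-F distribution of log variances (the `squeezeVar` scheme; the
   implementation matches Bioconductor limma to ~1e-10 on shared
   fixtures). When the between-gene spread of log variances does not
   exceed sampling noise the prior df is infinite and the common
   posterior variance is the mean observed variance. The linear model is
   summarized by a moderated F over its four stage coefficients (one
   significance per gene, as the study reports one adjusted p per model),
   the ordinal model by the moderated t of its slope; both p-value sets
   are Benjamini–Hochberg adjusted.
5. **Consensus.** Genes are ranked per model by ascending adjusted p,
   with ties broken by raw p, then descending |lfc|, then gene id. The
   consensus is the intersection of the two top-15 lists restricted to
   genes with adjusted p < 1e-5 in both models.
6. **Boruta.** Shadow-feature selection re-implemented on a random
   forest: each iteration appends shuffled copies of the candidate
   features (at least ten shadows, and at least twice the number of
   candidates — a deliberately strict null bar), counts a hit when a real
   feature's importance beats the best shadow, and decides features by
   two-sided binomial tests at α = 0.05, Bonferroni-corrected across
   features. Confirmation is additionally corrected for the sequential
   looks (one test per iteration); without this, chance hit streaks
   confirm spurious features. Rejection stays per-look. Features
   undecided at the iteration cap are tentative and are not selected.
   Features are processed internally in sorted-id order with
   per-(seed, iteration) RNG streams, so results are invariant to input
   column order.
7. **RFE.** Backward elimination, least-important-first by random-forest
   importance, with every subset size scored by stratified 5-fold CV
   accuracy (pooled over folds; the per-fold elimination order is refit
   on that fold's training part). The best-scoring size wins; **exact
   ties keep the larger subset**. On strong marker panels CV accuracy
   saturates, and resolving ties toward smaller subsets would discard
   informative markers on score noise alone; for an all-relevant
   biomarker panel a feature is discarded only when a smaller panel
   predicts strictly better.
8. **VIF.** Per round, each feature is regressed (with intercept) on all
   the others; `VIF = 1 / (1 − R²)`, with `R² ≥ 1 − 1e-12` reported as
   +∞. While the maximum VIF exceeds 2.0, that feature is removed (ties
   to the lexicographically smallest id) and the round repeats.
9. **PCA and component count.** Eigendecomposition of the sample
   covariance (centered, not scaled — the published eigenvalue sum of the
   nine-marker panel is far above nine, which rules out correlation-matrix
   PCA). Sign convention: each loading's largest-magnitude entry is
   positive. Component count reconciles three criteria by their median:
   Kaiser–Guttmann (λ > 1), the scree elbow (largest perpendicular
   distance to the chord joining first and last eigenvalues), and the
   smallest count with cumulative variance ≥ 85%.
10. **k-means classifier.** The silhouette method scans k = 2..8
    (seeded k-means, 10 restarts each) as a check; the classifier itself
    is k = 2 in the retained PC space, each cluster mapped to its
    majority training class (an error if both clusters map to one class).
    Prediction projects a sample onto the training loadings after
    centering with the training means; linear-scale input is first mapped
    through log2(x + 1). The margin score is
    d(normal centroid) − d(cancer centroid): positive predicts cancer,
    an exactly equidistant sample is conservatively called normal, and
    the margin feeds the rank-based AUROC (a hard clustering otherwise
    has no score).
11. **Evaluation.** 5-fold stratified CV on the training set refits PCA,
    the component choice, and k-means inside every fold and pools the
    held-out predictions; the untouched test split is scored once.
    Cancer is the positive class. Reports round percentages to two
    decimals (half-even).

## Synthetic cohorts

The generator emulates an RSEM-normalized cohort of controls plus stage
I–IV tumors; all default counts and rates are fixed as the package's
study conditions:

* 30 controls and (60, 120, 60, 30) tumors per stage — 300 samples with
  90% cancer imbalance and a stage-II-heavy distribution;
* 2,000 genes: 5 linear-signal, 4 ordinal-signal, 50 near-constant
  "flat" genes (sd 0.1 on the output scale, guaranteed victims of the
  σ < 1 filter), the rest null;
* log2 expression is baseline 6.0 plus the planted effect plus Gaussian
  noise (sd 1.0); the linear value is `2^log2` times a per-sample library
  factor drawn from U(0.8, 1.25). Flat genes are drawn directly on the
  output scale and skip library scaling.
* linear-signal genes carry per-stage offsets
  `±effect_size · (1, 1, g, g)` with effect_size 2.5 and
  stage_gain g = 1.2; ordinal genes carry slope
  `±effect_size · g / 4` per stage unit, so both gene types reach the
  same ±3.0 log2 offset at stage IV. Signs alternate, giving a near-even
  up/down split.

The early-stage offset (2.5 log2 units against sd 1.0) is deliberately
diagnosis-dominant: strong clinical markers show cancer-vs-normal
fold-changes that dwarf their progression gradient, and a generator with
a steep stage gradient instead produces a k = 2 clustering that splits
early from late tumors rather than cancer from normal. The mild gain
(1.2) retains the monotone progression structure the ordinal model
exists to detect while keeping the planted markers mutually
near-independent (pairwise VIF ≈ 1.3–1.7, matching the low
multicollinearity reported for real panels).

What the synthetic cohorts do **not** emulate: negative-binomial count
noise, batch effects, tumor subtypes or purity variation, correlated
co-expression modules, and heavy-tailed residuals. Passing tests
demonstrate that the pipeline's machinery is correct and recovers planted
structure under a clean log-normal model — not that the discovered panels
or accuracies would transfer to real tumor cohorts.

## Numerical choices and conventions

* Stratified-count rounding: half away from zero (the study's printed
  counts do not pin a convention; this one is documented and tested).
* Published variance tables accumulate their own rounded percentage
  column (67.24 + 14.00 + 5.43 = 86.67, where exact arithmetic gives
  86.68); the reference checks reproduce the printed cumulative values
  under that convention while the library itself returns exact running
  sums.
* k-means: Euclidean Lloyd iterations, 10 seeded restarts, tol 1e-6.
* Degenerate inputs raise typed errors rather than propagating NaNs:
  zero-library samples, constant features in VIF/PCA, single-class
  labels, missing stages in the indicator design, all-zero residual
  variances.
* All randomness flows from integer seeds; equal seeds give bitwise-equal
  cohorts, splits, selections, and fitted models.

## Problem sizes

Tests run the full pipeline on reduced cohorts (400 genes, 180 samples)
and the acceptance script on the default 2,000-gene, 300-sample cohort;
these sizes exercise every stage at full fidelity while a discovery run
completes in well under a minute on one CPU.

## Known limitations

* The adjusted-p gate (1e-5) is calibrated for cohorts of hundreds of
  samples; at a few dozen samples the consensus can legitimately come up
  empty, which surfaces as a stage error rather than a silent empty
  panel.
* With ~25 training controls per fold, the cluster-to-class mapping can
  fail when a fold's clustering does not isolate the controls; this is
  reported as an error, not absorbed.
* Boruta decisions on cohorts with strong chance correlations (small n,
  many candidate features) remain anti-conservative in principle; the
  doubled shadow pool and sequential-look correction mitigate but cannot
  eliminate this.
* AUROC is computed from the centroid-margin score; other score
  conventions for hard clusterings would give different AUROCs with the
  same hard assignments.
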