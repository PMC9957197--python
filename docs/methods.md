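# Methods

## Scope and data model

The pipeline operates on a `FeatureTable`: n samples × p volatile
compounds, concentrations in µg/kg, one region label per sample, and a
boolean "not detected" (nd) mask. nd cells are *structural* zeros: they are
stored as 0 (so matrix operations are well defined) but remain
distinguishable from measured zeros, because log-ratios are undefined for
them and presence/absence is itself information. Compound metadata carries
the literature odor threshold in water (µg/L); concentrations are divided
by thresholds without a density correction, the usual convention for
water-rich fruit matrices (> 80 % water), and a caveat any OAV reader
should keep in mind.

## Quantification

* **Kovats retention index.** `RI = 100·n + 100·(t_a − t_n)/(t_{n+1} − t_n)`
  between the bracketing C_n and C_{n+1} alkanes of a C7–C40 ladder.
  Strictly interpolating: times outside the ladder raise an error rather
  than extrapolate, since the linear law only holds between brackets. If a
  ladder skips alkanes, interpolation spans 100 index units per skipped
  carbon.
* **Internal-standard semi-quantification.** `C = (A_c/A_i)·C_i` with the
  2-butanol default `C_i = 2.70 mg/L`. This is a one-point response model:
  it assumes equal response factors, so outputs are semi-quantitative.
* **OAV screen.** OAV = concentration/threshold, computed from per-region
  mean concentrations. The default screening rule is *any-region* (OAV > 1
  in at least one region makes a compound aroma-active): in the reference
  data, nonan-1-ol and 5-ethyloxolan-2-one exceed threshold in only one
  region yet belong to the aroma-active set, which only the any-region rule
  reproduces. An all-regions rule is available.

## Preprocessing

Columns are centered and Pareto-scaled (divide by √SD, sample SD with
n−1). Pareto scaling moderates the dominance of high-abundance volatiles
without inflating near-noise columns the way unit-variance scaling does.
Unit-variance and center-only modes are provided; `unit_variance` exists
partly so the alternative reading of the scaling formula (divide by SD) is
also executable. Constant columns are flagged, scaled by 1 and zeroed.
Inside cross-validation the transform is always refit on the training fold
and applied frozen to the held-out rows — re-estimating on test rows leaks
information and inflates Q².

## Latent-variable models

All fits are NIPALS (convergence when the score changes by < 1e−10,
max 500 iterations).

* **PCA** for unsupervised overview; loadings match the SVD up to sign.
* **PLS-DA**: per component `w ∝ Xᵀy` (unit norm), `t = Xw`,
  `c = yᵀt/tᵀt`, `p = Xᵀt/tᵀt`, then deflation of X and Y. Two-class Y is
  a single centered 0/1 column (1 = lexicographically second label); K > 2
  classes use centered one-hot columns and the iterative NIPALS inner loop.
  If Y is orthogonal to every X column (‖Xᵀy‖ < 1e−10) a null component is
  emitted rather than dividing by ~0.
* **OPLS-DA**: per orthogonal component `w_o ∝ p − (wᵀp)·w`, normalized;
  `t_o = X w_o`, `p_o = Xᵀt_o/t_oᵀt_o`, deflate; finally one predictive
  component on the filtered matrix. Pairwise models are fixed at
  1 predictive + 1 orthogonal component — the structure of all three
  reference models — and automatic component selection is deliberately out
  of scope. The predictive score is oriented so its positive side is the
  class coded 1. The Frobenius decomposition
  R²p(X) + R²orth(X) + residual = 1 is exact (enforced to 1e−8 in tests)
  because t ⊥ t_o and E is orthogonal to both.

**Cross-validation.** Stratified 7-fold by default: within-class seeded
shuffle, then one global round-robin deal across classes, giving fold sizes
differing by at most one overall and per class (24 samples → 4,4,4,3,3,3,3).
Each fold refits scaling and model on the training rows; Q²(Y) =
1 − PRESS/SS with SS the total centered Y sum of squares. Folds whose
training set lacks a class raise an error advising fewer folds.

## Diagnostics

* **S-plot.** `p(cov)_j = tᵀx_j/(N−1)`, `p(corr)_j = p(cov)_j/(σ_t σ_xj)`
  (identically the sample correlation). The published-style cutoff
  |p(cov)| ≥ 0.1 needs a scale convention because raw covariances are
  data-dependent; here the covariance vector is normalized to unit
  Euclidean norm before thresholding (≈ "this variable carries ≥ 1 % of the
  squared covariance mass"), with raw covariances retained for plotting.
  This is a documented assumption, configurable via the config thresholds.
* **VIP.** `VIP_j = sqrt(p · Σ_a SSY_a w_aj² / Σ_a SSY_a)` over
  *predictive* components only (the OPLS convention for discriminating
  variables), so Σ VIP² = p exactly; p counts all model columns, including
  constant ones whose weight is zero.
* **Jack-knife CIs.** Per-fold predictive loadings are sign-aligned to the
  full-model loading (NIPALS sign indeterminacy would otherwise inflate
  the spread), then `SE_CV = SD(fold loadings)/√folds` and
  `half width = SE_CV · t(α/2, folds−1)` (two-sided, α = 0.05 → t = 2.447
  at 7 folds). Identical fold loadings give exactly zero width.
* **Permutation test.** Each of the n_perm label permutations triggers a
  full refit including cross-validation; the (|corr with true y|, R², Q²)
  cloud plus the unpermuted point at correlation 1 define least-squares
  lines whose value at correlation 0 gives the R² and Q² intercepts. A
  model is declared valid when its R² and Q² exceed every permuted value
  *and* the Q² intercept is negative. Both intercepts are reported since
  conventions differ on which one to quote.
* **SUS plot.** For two OPLS models sharing a reference class, each
  compound sits at (p(corr)₁, p(corr)₂), oriented so positive means
  elevated in the non-reference class. Classification: shared if
  |p(corr)| ≥ 0.5 in both; unique to one model if ≥ 0.5 there and ≤ 0.2
  (the numeric reading of "close to zero") in the other; otherwise
  uninformative.

## Marker selection

Per pairwise contrast, a compound is a candidate iff it passes all four
filters: S-plot selection, VIP > 1, Welch t-test p < 0.05 and
|log₂ FC| > 1. Welch rather than pooled t because group SDs in such data
differ up to ~10×. No multiple-testing correction by default (matching
common practice of raw p < 0.05 in this workflow); a Benjamini–Hochberg
flag could be added at the univariate stage without changing interfaces.
Compounds detected in only one region have undefined log-FC; they pass the
FC filter only when the detected-region mean exceeds 3× its SD and are
annotated qualitative. In the reference scenario these region-specific
compounds are excluded by the VIP filter (their absolute scale is small)
and would fail the OAV intersection regardless. The final panel is the
union of pairwise candidate sets intersected with the OAV-active set.

## Origin classifier

Multi-class PLS-DA (centered one-hot Y) with 2 latent variables on the
panel compounds; prediction is the argmax of the predicted uncentered Y
columns, with exact ties broken toward the earliest class label and logged.
2 LVs mirror the reference model; an optional PRESS-minimizing auto-selector
exists behind a flag. Both training and cross-validated summaries are
reported because published "100 % accuracy" claims rarely say which one
they are.

## Synthetic data generator

The generator emulates the reference study design: 3 regions × 23
compounds, 12 composite samples per region (the study pooled 48 field
samples per region four-to-one), each detected cell drawn i.i.d. from a
normal distribution with the published cell mean and SD, truncated at zero;
not-detected cells are exact zeros with the nd mask set. Truncated normal
rather than lognormal because the published summaries are arithmetic
mean ± SD with small CVs (< 25 %), making truncation distortion negligible
(at the most extreme cell, mean/SD ≈ 4, the truncated mass is < 0.01 %);
a moment-matched lognormal mode exists for robustness studies. Rows are
deterministically shuffled; everything is reproducible from the seed.

What the generator does **not** model: between-replicate technical
structure (the published SDs already aggregate it), compound–compound
correlations within a region (cells are independent), batch/instrument
drift, and censoring near detection limits. Passing tests therefore show
the pipeline recovers markers when between-region effects dominate
independent within-region noise at the published effect sizes (3–40× SD) —
not that it would do so under correlated or drifting real-world noise.

## Problem sizes and numerical choices

Default test and acceptance runs use 36-sample tables (12 per region),
7-fold CV and 50-permutation validation for multi-seed sweeps (200 is the
single-run default), chosen as the package's standard quick-verification
settings. Tolerances: NIPALS convergence 1e−10; variance-conservation and
VIP normalization asserted to 1e−8; scaling round-trip to 1e−8 relative.
Degenerate inputs are handled explicitly: single-sample regions are flagged
rather than given fake SDs, zero-variance columns are excluded from
correlation-based diagnostics and never selected, zero-variance Welch
comparisons return p = 1 when means agree, and identical jack-knife fold
loadings give exactly zero interval width.

## Known limitations

* The S-plot covariance cutoff's unit-norm convention is an assumption;
  other software thresholds on differently scaled loadings, so candidate
  sets near the 0.1 boundary can differ between implementations.
* OPLS-DA here is two-class with one predictive component by design;
  multi-class discrimination goes through the PLS-DA classifier instead.
* OAVs use literature thresholds in water; matrix-specific threshold
  correction is out of scope.
* The reference per-region summaries are published rounded values; four
  cells of the published OAV table differ in the last digit from the
  quotient of the published concentration and threshold, and the package
  reproduces the quotient, not the misprint.
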