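# Methods

This note documents the generating model, the analysis procedures, the
defaults and the reasoning behind them, numerical choices, and known
limitations.  It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute.

## Synthetic cohort generator

The generator (`regionage.simulate`) emulates a population-imaging cohort
of middle- and older-aged women.

**Demographics.** Age is truncated normal, mean 63.59, SD 7.38, bounds
[45.13, 82.27] (sampled by inverse-CDF through `scipy.stats.truncnorm`;
this is equivalent to rejection sampling and loop-free).  Parity (number
of live childbirths, 0–9) is multinomial with the reference per-parity
proportions (4,297 : 2,459 : 8,770 : 3,334 : 729 : 142 : 43 : 7 : 5 : 1
over 19,787), giving mean 1.72 and SD 1.16.  Scan site (3 levels),
ethnicity, education and menopausal status use the reference margins.
Covariate distributions not characterized by the reference demographics
(BMI, smoking, alcohol, OC/HRT use, diabetes, hypertension, age at first
birth) use plausible values chosen once for face validity; they exist so
that covariate-adjusted regressions are exercised, not to be faithful.
Parity is missing completely at random (default rate 9/19,796; an exact
count can be requested).

**Regional volumes.** Each of 43 hemisphere-averaged regions (expanded to
85 raw columns with a fixed ±1% left/right asymmetry) follows

v = baseline + s·(age − µ_age) + e·births + c_icv·(ICV − µ_icv)
    + c_qc·(QC − µ_qc) + site offset + ε,

with baselines at typical FreeSurfer volumes (mm³), age slopes
s = −0.25%/yr (cortical) and −0.3%/yr (subcortical) of baseline, and
residual SD = 1.5·|s|·SD(age), so a single region predicts age with
r ≈ 0.55 and cluster models land near r ≈ 0.6.  (Real single-region
accuracies are somewhat lower, ~0.2–0.5; the higher signal-to-noise was
chosen, once, so that desk-scale cohorts of n = 5,000 retain adequate
power; see "Effect scale" below.)  Nuisance loadings default to nonzero
values (ICV ~30% proportional scaling, QC 0.05% of baseline per unit,
site ±0.5% of baseline) so residualization is exercised.

**Covariance blocks.** ε is multivariate normal with an equicorrelated
nested block structure: correlation 0.8 within a sub-block, 0.5 between
the two sub-blocks of the temporo-subcortical block, 0 across blocks.
The five blocks are the five-region-group partition in
`regionage.atlas.CLUSTER_OF_REGION` (posterior/occipito-parietal;
fronto-central; temporal + striatal/limbic; anterior cingulate & poles;
brain stem/cerebellar + remaining basal ganglia — sizes 7/16/11/5/4),
with the third block split into a cortical-temporal and a
striatal/limbic sub-block.  Hierarchical clustering on the residualized,
hemisphere-averaged features therefore has an unambiguous ground truth.

**Exposure effect.** The default effect is confined to the six
striatal/limbic regions and expressed in *years of aging equivalent per
childbirth*: the volume offset per birth is −s·y, i.e. each birth
preserves y years of age-related decline.  Defaults: accumbens y = 2.2,
the five other regions y = 1.98 (ratio 0.9).  Two deliberate choices:

- *Ratio 0.9 (redundancy point).*  In the leave-one-region-out
  log-likelihood test, a region contributes *unique* information exactly
  to the extent that its effect deviates from what the other (correlated)
  regions predict; for this covariance structure the deviation vanishes
  near a non-focal/focal effect ratio of 0.9 (located by pilot
  simulation).  At that point the five non-focal regions are clearly
  associated with the exposure marginally, yet carry essentially no
  information beyond the accumbens — the qualitative pattern the method
  is designed to detect (focal effect, correlated neighbours).
- *Effect scale.*  y ≈ 2 years/birth is roughly 5–8× the effect sizes
  reported in real cohorts of n ≈ 20,000.  The scale was set, before any
  acceptance checks were frozen, so that a single n = 5,000 cohort gives
  high design power for (a) the focal cluster having the most negative
  association, (b) the correlated-estimates Z test separating it from
  every unaffected cluster, and (c) the accumbens' unique contribution in
  the nested test.  Real-world effect sizes are not recoverable at desk
  scale; the generator's role is to give the pipeline a detectable truth,
  not to reproduce published magnitudes.

Sampling is fully vectorized from one `numpy` Generator; identical
configs (including seed) give bit-identical tables.

## Preprocessing

- "SD ± 4" outlier exclusion is read as strict |z| > 4 (a point at
  exactly 4 SD is retained).  z-scores are computed on the sample after
  the diagnosis exclusion but before the metric exclusions; the retained
  set is the complement of the union of all flags, so evaluation order
  cannot matter, and the QC report gives per-flag counts alongside the
  union.
- The two per-hemisphere quality scores are averaged into one score per
  participant before thresholding.
- Residualization regresses every feature on intercept + site + averaged
  QC score + ICV + ethnicity (categoricals one-hot with the first level
  dropped), with non-intercept design columns standardized for
  conditioning (ICV is ~10⁶ mm³).  Residuals are exactly orthogonal to
  the design; the operation is idempotent.  A rank-deficient design is
  rejected with the offending columns named.
- Residualization precedes hemisphere averaging and is fitted on the full
  analysis sample (see the leakage note in the README).

## Clustering

Distance 1 − ρ (Spearman), average linkage, cut to an exact k by
`scipy.cluster.hierarchy.fcluster(..., criterion="maxclust")`; k is a
parameter (defaults 5 top-level, 2 for sub-clustering) — no automatic cut
criterion is invented.  Ranks use the mid-rank convention for ties
(scipy's default), making the whole stage invariant to strictly monotone
transforms of any feature.  Labels are renumbered 1..k in order of first
appearance, so only the partition, not the numbering, is data-determined.
The two-column case, which scipy collapses to a scalar, is handled
explicitly.

## Brain-age models

The boosted-tree engine is pluggable behind a fit/predict contract:

- `engine="xgboost"` — reference engine; defaults max depth 6,
  140 estimators, learning rate 0.1 (the tuned optimum of the original
  randomized search), `tree_method="hist"`, single-threaded, seeded.
- `engine="hist"` — scikit-learn `HistGradientBoostingRegressor`; the
  packaged `FAST_PARAMS` (depth 3, 60 iterations, rate 0.1) are used for
  Monte-Carlo studies where thousands of fits are needed.

Randomized hyperparameter search (`tune_params`) samples the space
{max depth 3–12} × {estimators 60–220 step 40} × {rate 0.1, 0.01, 0.05}
and scores candidates by cross-validated MAE on a shared fold partition.

Fold assignment is a seeded, balanced random partition.  One partition is
reused across all feature sets of a run so cluster-, subcluster- and
region-specific deltas are computed on identical folds and the
correlated-estimates comparisons are meaningful.  Out-of-fold predictions
guarantee each participant's estimate comes from a model that never saw
their fold; the delta is predicted − chronological age, exactly.

Accuracy metrics: Pearson r with Fisher-z 95% CI (half-width
1.96/√(n−3) on the z scale), R² = 1 − SSres/SStot, RMSE, MAE.
Permutation feature importance (mean R² drop over seeded shuffles of one
column at a time) delegates to `sklearn.inspection.permutation_importance`.

## Association statistics

- **Age-bias correction**: residual of delta on intercept + age; the
  output is exactly uncorrelated with age.  The exposure coefficient from
  `delta ~ exposure + age` equals the one from corrected-delta ~
  corrected-exposure (Frisch–Waugh), which the tests assert to 1e-8.
- **Exposure regression**: OLS with classical SEs, two-sided p; supports
  the extended covariate set; rank-deficient designs are rejected with
  the collinear columns named.
- **Correlated-estimates Z**: Z = (β₁ − β₂)/√(σ₁² + σ₂² − 2ρσ₁σ₂), with ρ
  operationalized as the Pearson correlation between the two feature
  sets' age-corrected delta vectors — the quantity that induces
  dependence between the two slope estimates.  ρ is an explicit argument,
  so alternative definitions can be supplied.  Two-sided normal p.
- **BH-FDR**: `statsmodels.multipletests(method="fdr_bh")` behind
  `fdr_adjust`; unit tests verify it against a literal brute-force
  step-up implementation (p_adj(i) = min over ranks j ≥ rank(i) of
  p(j)·m/j, capped at 1).
- **Polynomial group fits**: parity groups with exposure ≥ 6 pooled at
  their count-weighted mean; group SE = SD/√n; weighted least squares
  (weights 1/SE²) for degree-1 and degree-2 models; overall F per model
  against the weighted-mean null and an F comparing the two; the degree-2
  fit is also reported in a weighted-orthonormal polynomial basis (QR of
  the √w-scaled Vandermonde, signs fixed for reproducibility), which
  leaves fitted values and the comparison F unchanged.  Exact fits
  (zero weighted RSS) return F = ∞ with p = 0, and a numerically zero
  numerator returns F = 0.
- **Nested log-likelihood comparison**: Gaussian OLS log-likelihoods of
  exposure on all region deltas vs each leave-one-out reduction;
  ΔLL = LL_full − LL_reduced (clipped at 0 against roundoff);
  Z = √(2ΔLL); p from the χ²(1) tail per Wilks' theorem (1 parameter
  dropped); BH adjustment across regions.
- **Group contrast**: OLS of delta on a parity indicator + age; Cohen's d
  from age-corrected deltas with pooled SD and the large-sample
  SE √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))); d carries the sign of the
  contrast.

All p-values are two-sided; no robust-SE options are exposed.

## Monte-Carlo studies

`regionage.experiments` provides seeded calibration and recovery studies:

- Null calibration of the exposure regression (delta pure noise) and of
  the Z test (two correlated delta vectors with equal true slopes),
  2,000 replicates of n = 500 by default; both should reject at
  5% ± Monte-Carlo noise.
- The recovery study runs the full pipeline on 20 cohorts of n = 5,000
  with the default localized effect and scores three conditions per
  replicate: focal cluster ranked most negative; Z significant against
  every unaffected cluster; accumbens uniquely flagged by the nested test
  at BH q < 0.05.

A statistical property of the third condition deserves note: with one
strongly contributing region and five truly redundant ones, the BH
procedure at q = 0.05 still flags at least one redundant region in
roughly 8–10% of replicates — this follows from BH's own FDR guarantee
(E[V/(V+1)] ≤ q·m₀/m implies P(V ≥ 1) up to ≈ 2q·m₀/m) and is not
removable by any choice of generator parameters.  Per-replicate
uniqueness rates just above 90% are therefore the ceiling for this
design, and observed rates fluctuate accordingly across seeds.

## Problem sizes

Default study sizes — n = 5,000 cohorts, 20 recovery replicates, 2,000
calibration replicates, and the fast boosting engine for repeated fits —
were chosen as the package's own desk-scale conditions; all are
parameters.

## Limitations

- The generator is linear and Gaussian: no nonlinear aging trajectories,
  no site-by-age interactions, no heavy tails, no realistic missingness
  beyond MCAR parity, and covariate distributions are placeholders.
  Passing tests demonstrate correctness of the machinery under these
  conditions, not performance on real data.
- Exposure effects are power-scaled (~5–8× realistic magnitudes); real
  effects at n = 5,000 would rarely be detectable.
- Residualization on the full sample leaks mild information across CV
  folds (documented in the README).
- The χ²(1) reference for the nested comparison is asymptotic; at small n
  an exact F test would differ slightly.
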