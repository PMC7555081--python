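# regionage

Regional brain-age modelling of parity-linked brain aging, with a
synthetic-cohort generator standing in for restricted population data.

## The problem

Brain-age prediction estimates a person's age from structural brain
features; the **brain-age delta** (predicted minus chronological age)
measures deviation from normative aging — positive values mean
older-looking brain structure.  Large population studies of women in
mid/late life (UK Biobank scale, n ≈ 20,000) have related the delta to the
number of live childbirths, finding *less* apparent brain aging with
higher parity, concentrated in striatal and limbic regions and strongest
in the accumbens.  Testing such *regional* hypotheses requires a pipeline
that goes beyond a single global brain-age model:

1. **QC and nuisance control** — exclude flagged diagnoses, |z| > 4
   outliers on surface-quality (Euler-number) scores and on global
   gray-matter means, and participants missing the exposure; residualize
   the 85 regional volumes (68 Desikan–Killiany cortical, 17 subcortical)
   on scan site, quality score, intracranial volume and ethnicity;
   average hemispheres to 43 regions.
2. **Covariance clustering** — group regions by agglomerative clustering
   (average linkage) on the distance 1 − ρ, ρ the Spearman rank
   correlation; cut at k = 5, and sub-cluster the most strongly
   associated cluster at k = 2.
3. **Cluster-specific brain age** — per feature set (cluster, subcluster,
   single region), a gradient-boosted tree regressor (XGBoost; defaults
   max depth 6, 140 estimators, learning rate 0.1, tuned by randomized
   search with 10 folds / 10 iterations) produces out-of-fold predictions
   under shared 10-fold cross-validation; accuracy is reported as
   Pearson *r* (Fisher-z 95% CI), R², RMSE and MAE.
4. **Inference on deltas** — OLS of delta on exposure with age (and
   optionally site, education, BMI, diabetes, hypertension, smoking,
   alcohol, menopausal status, OC/HRT use) as covariates; BH-FDR across
   feature sets; pairwise comparison of two slopes estimated on the same
   participants by the correlated-estimates Z test

   Z = (β₁ − β₂) / √(σ₁² + σ₂² − 2ρσ₁σ₂),

   with ρ the correlation between the two age-corrected delta vectors;
   weighted polynomial fits (weights 1/SE²) to parity-group means of
   age-corrected deltas; a parous/nulliparous contrast with Cohen's *d*;
   and a leave-one-region-out log-likelihood comparison of nested OLS
   models, read through Wilks' theorem (Z = √(2ΔLL), χ²(1) tail).

Because the cohort data are restricted, the package ships a first-class
synthetic generator (`regionage.simulate`) that reproduces the cohort's
marginal structure (age 63.6 ± 7.4 years in [45.1, 82.3]; parity
multinomial with mean 1.72, SD 1.16; site/ethnicity/education margins),
block-structured covariance across regions matching the five-cluster
partition, nuisance loadings, and a localized, power-scaled parity effect
in the striatal/limbic sub-block, strongest in the accumbens.  Every
stage of the pipeline is therefore testable against a known ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end; each is
a thin driver over the library.  `python analysis/04_run_pipeline.py`
(n = 5,000 synthetic cohort, fast histogram-boosting engine) prints:

```
analysed n = 4995

cluster-specific exposure associations (delta ~ births + age):
  cluster 1: n_feat=11 r=0.60 beta=-0.353 se=0.041 t=-8.52 p_adj=1.06e-16 *
  cluster 2: n_feat= 5 r=0.57 beta=+0.006 se=0.041 t=+0.15 p_adj=8.77e-01
  cluster 3: n_feat=16 r=0.58 beta=+0.021 se=0.041 t=+0.50 p_adj=7.69e-01
  cluster 4: n_feat= 7 r=0.57 beta=-0.042 se=0.041 t=-1.02 p_adj=5.14e-01
  cluster 5: n_feat= 4 r=0.55 beta=+0.065 se=0.040 t=+1.61 p_adj=2.69e-01

subcluster associations:
  subcluster 1 (bankssts, fusiform, ...):                    beta=-0.006 t=-0.14
  subcluster 2 (parahippocampal, thalamus, ..., accumbens):  beta=-0.635 t=-16.22
subcluster comparison: Z=+17.08 (rho=0.58, p=1.93e-65)
parous vs nulliparous: beta=-1.422 (0.111), d=-0.436 +/- 0.034

leave-one-region-out log-likelihood comparison:
                 delta_ll      z         p     p_adj
parahippocampal     0.072  0.380  0.704140  0.844967
thalamus            0.206  0.641  0.521369  0.844967
putamen             0.075  0.387  0.699104  0.844967
hippocampus         1.499  1.731  0.083402  0.250207
amygdala            0.019  0.194  0.846100  0.846100
accumbens           9.150  4.278  0.000019  0.000113
```

Reading this: the temporo-subcortical cluster (cluster 1 here; labels are
data-determined) carries the only significant negative association of
brain-age delta with number of childbirths; within it, the
striatal/limbic subcluster dominates (Z = 17 against the cortical
subcluster); and among its six regions only the accumbens contributes
information about parity beyond the other five (BH-adjusted p = 1.1e-4),
even though all six are marginally associated — exactly the planted
structure.  The deltas are in years per childbirth; the negative sign
means more childbirths → younger-looking brain structure.

`05_replication_split.py` demonstrates the replication design (global
model trained on one half, association tested on the held-out half);
`06_null_calibration.py` and `07_effect_recovery.py` run the Monte-Carlo
calibration and recovery studies.

## A note on residualization and leakage

Following the original design, nuisance residualization is fitted on the
full analysis sample *before* any train/test split.  This induces a small
information leak across folds (the nuisance fit sees all participants).
It does not touch age or the exposure, so its effect on the association
estimates is negligible, but strict out-of-sample deployment would fit
the residualization on training folds only.
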