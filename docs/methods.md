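# Methods

`habitatus` implements a habitat-based bi-modal ultrasound radiomics
pipeline for predicting axillary lymph node (ALN) burden — low (0–2
metastatic nodes) versus high (≥3) — in early-stage breast cancer, and a
synthetic-data generator that makes every stage testable without patient
data. This note records the models, the defaults and why they were
chosen, and what the synthetic experiments do and do not demonstrate.

## Pipeline

For each lesion the inputs are a B-mode ultrasound (BMUS) image, a
shear-wave elastography (SWE) stiffness image on a 0–180 kPa display
scale, a binary lesion ROI drawn on the BMUS frame (transferred to the
SWE panel by pure XY translation), a clinical covariate record, and the
binary burden label. The stages are:

1. **Per-pixel clustering features** (`habitat.pixel_features`). Ten
   channels per ROI pixel over a `window × window` neighbourhood
   intersected with the ROI: six GLCM statistics (contrast,
   dissimilarity, homogeneity, energy, correlation, angular second
   moment) from a symmetric normalised co-occurrence matrix pooled over
   the four distance-1 directions; Shannon entropy of the quantised
   histogram; mean and SD of the uniform 8-neighbour LBP code; and the
   windowed mean of the grayscale morphological closing (disk radius 2).
   Defaults: window 7, 32 gray levels. Degenerate (constant) windows take
   analytic limits — entropy 0, contrast 0, energy 1, correlation 0 (its
   0/0 limit), lbp_std 0 — so the stack is always finite. Co-occurring
   pairs are attributed to their anchor pixel; a pair counts when the
   anchor is inside the window and both endpoints are inside the ROI.
2. **Habitat segmentation** (`habitat.segment_habitats`). Channels are
   z-scored per lesion, K-means (k-means++, 10 restarts, 300 iterations,
   tol 1e-4, fixed seed) is run for k = 2…10, and each clustering is
   scored with five validity indices: Calinski–Harabasz, inertia,
   Davies–Bouldin, separation (mean between-centroid distance) and mean
   intra-cluster distance, the last normalised by the total point count
   (so it decays in k by construction). k is chosen by rank aggregation
   over the three indices with interior optima — CH and separation
   (higher better) and DBI (lower better); inertia and mean intra-cluster
   distance decrease monotonically in k and do not vote; ties go to the
   smaller k. Habitat labels are renumbered by ascending mean intensity
   (brightness for BMUS, stiffness for SWE) so "habitat 1" is comparable
   across lesions. For feature-table construction the habitat count is
   fixed per modality (defaults k_BMUS = 4, k_SWE = 5), giving a uniform
   column schema; per-lesion free selection remains available.
3. **Radiomics** (`radiomics.extract_features`). 927 named features per
   (image, region): 103 per band — 10 shape, 18 first-order, 24 GLCM,
   14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM — on the original image and on
   eight wavelet bands. The 2-D image is treated as a one-slice volume
   and decomposed with single-level undecimated coif1 filters along all
   three axes; along the length-one slice axis the high-pass factor is
   identically zero (the analytic consequence of a single slice), so
   slice-high-pass bands carry constant-image feature values. Shape
   features depend only on the mask and repeat across bands — this is
   the only accounting consistent with 927 = 103 + 8×103 and is
   toggleable. Texture quantisation uses a fixed bin count (32).
4. **Selection** (`selection`). On training rows only: a Pearson
   correlation filter (|r| > 0.9; survivors chosen by a deterministic
   greedy rule that drops the column most correlated with the remainder),
   then L1-penalised logistic regression with the penalty chosen by
   10-fold cross-validated deviance over a 100-point log-spaced grid and
   coefficients below 1e-6 discarded. The **one-standard-error rule** is
   the default: the plain CV minimum is notoriously permissive as a
   screening rule — on a planted problem (3 informative among 500 noise
   columns, n = 200) CV-min admits 15–70 noise columns (confirmed
   independently with R's `cv.glmnet`, which keeps 15 at `lambda.min`
   versus 6 at `lambda.1se` on identical data), while 1-SE keeps the
   informative triple with a handful of false positives. If 1-SE zeroes
   every coefficient the CV minimum is used as fallback; `rule="min"` is
   available.
5. **Modeling** (`modeling`). Eleven classifiers (LR, NaiveBayes, SVM,
   KNN, RandomForest, ExtraTrees, XGBoost, LightGBM, GradientBoosting,
   AdaBoost, MLP) with library-default hyperparameters and fixed seeds;
   scale-sensitive models are wrapped with a standardiser. Reports carry
   AUC with a stratified-bootstrap 95% CI (2000 resamples by default),
   accuracy, sensitivity/recall, specificity, PPV/precision, NPV and F1
   at an operating threshold fixed on the training ROC by Youden's J
   (taken at the midpoint between adjacent score thresholds, which is
   robust when the optimal cut falls exactly on an observed score).
6. **Clinical statistics** (`clinstats`). Pearson χ² *without* continuity
   correction (the variant consistent with the reference
   cross-tabulations), Fisher's exact test (probability-mass summation),
   and the pooled-variance t-test from group summaries. The
   clinicopathologic (C) model is a logistic regression on covariates
   passing a univariate screen (p < 0.05 on the training cohort, χ² when
   all expected counts ≥ 5, else Fisher).
7. **Split** (`dataio.split_cohort`). Stratified by burden; the test
   cohort holds ⌈(1−ratio)·n⌉ cases apportioned by largest remainder, so
   206 cases at 80:20 give 164/42. The default split seed is 10000.

## Synthetic data

`synthdata.generate_cohort` emulates the data regime the pipeline is
meant for; defaults are fixed once and shared by the tests.

* **Geometry.** A lesion is a random ellipse (semi-axes 18–36 px inside
  a 128×128 image, ≥3 px margin of surrounding tissue) partitioned into
  2–5 spatially contiguous habitats by a Voronoi tessellation of random
  interior seeds; draws are rejected until every cell holds at least half
  the average cell size. At a typical linear-probe resolution of
  ~0.1 mm/px these sizes correspond to sub-centimetre to ~1.5 cm lesions.
* **BMUS.** Habitat identity lives on two texture axes: echogenicity
  (mean level 70–120) and speckle-pattern grain (Gaussian correlation
  length 0.6–3.0 px at fixed texture SD 18), multiplied by Rayleigh-like
  multiplicative speckle (`speckle_sigma`, default 0.25). Equal texture
  SD keeps per-habitat feature spreads comparable, which K-means (an
  equal-variance method) needs.
* **SWE.** A scalar stiffness field (the display colormap is only a
  rendering of this scalar): per-habitat mean stiffness plus iid fine
  texture with habitat-specific amplitude, plus a smooth lesion-scale
  field (`swe_smoothness` = 4 px), clipped to [0, 180] kPa. The total
  lesion stiffness SD is set by `stiffness_contrast` (0.36 × contrast,
  bounded so habitat means stay on-scale) and split 75% between-habitat /
  25% within. All piecewise maps are softened by a resolution blur
  (σ = 2 px), mimicking finite elastographic resolution; without it the
  step transition creates a boundary ribbon of extreme windowed-texture
  values that clusters as a spurious extra habitat.
* **Clinical covariates and burden.** Covariate marginals follow a
  typical early-breast-cancer cohort (e.g. 52% cT2, 31% US-positive
  nodes, 78% ER-positive). Burden is logistic in cT2 (log-OR 0.75) and
  US-positive nodes (log-OR 1.0) — the two genuinely associated
  covariates — with the intercept calibrated to the configured
  high-burden fraction (default 0.316); all other covariates are
  independent of burden.
* **Burden image signal.** High burden changes the character of the
  *stiffest* habitat only: its fine-texture amplitude grows by
  `burden_contrast_boost` (default 0.6). Whole-lesion mean and total
  variance are deliberately uninformative; whole-lesion texture
  statistics see the effect diluted across habitats, while the stiffest
  habitat's feature slot (canonical ordering makes it the last slot)
  isolates it. This is the construction under which habitat features are
  expected to out-discriminate whole-lesion ("omics") features.

What the generator does **not** emulate: physical beam propagation,
attenuation and shadowing, RGB elastogram rendering, operator- and
device-dependent artefacts, 3-D structure, and histology-driven feature
correlations. Passing tests therefore demonstrate internal consistency
of the pipeline and recoverability of planted structure — not clinical
performance.

## Problem sizes and scaled experiments

Synthetic experiments are sized for a single CPU: recovery sweeps use
5 lesions per planted habitat count at strong contrast
(`stiffness_contrast` 90, speckle 0.02–0.05, lesion axes 40–64 px);
the model-comparison experiment uses 60–80 cases × 3 seeds; the
end-to-end run uses 60 cases with 96×96 images. Larger cohorts change
the variance of these estimates, not their construction.

## Known limitations

* **Validity-index k selection is unreliable beyond two habitats.** With
  two well-separated habitats the vote picks k = 2 and ARI against the
  planted map exceeds 0.9. For 3–5 planted habitats, boundary windows
  form genuine intermediate clusters in feature space and K-means'
  equal-variance bias merges close habitats while splitting
  heterogeneous ones; the vote then recovers the planted count in only a
  minority of lesions and cohort mean ARI plateaus near 0.6 under strong
  contrast. Extensive exploration (transition blurs, texture-amplitude
  and correlation-length spreads, window sizes 7–11, 16–32 quantisation
  levels, larger lesions) did not change this qualitatively: it is a
  property of clustering windowed texture features with validity-index
  model selection, not of a particular parameterisation. Real habitat
  analyses have no ground-truth subregions, so this limit is invisible
  in clinical applications of the method — but it bounds what "the
  optimal number of clusters" means quantitatively.
* **Whole-lesion radiomics is nearly a sufficient statistic.** The
  927-feature whole-ROI vector (percentiles, zone statistics, texture
  matrices) captures most constructions one might plant. On the
  model-comparison experiment the habitat-vs-whole-lesion ordering is
  seed-dependent: habitat features concentrate a subregion-localised
  effect into one feature slot, but fixed-k habitat maps add clustering
  noise, and across seeds the whole-lesion set comes out slightly ahead
  on average. A consistent habitat advantage should not be expected from
  this pipeline on data whose whole-lesion statistics carry the same
  information.
* Fixed-k habitat maps inherit the segmentation's noise; feature slots
  are comparable across patients only through the intensity-based
  canonical ordering.
* The wavelet slice-axis high-pass bands of a single-slice volume are
  identically zero; their features are retained for schema fidelity but
  carry no information.
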