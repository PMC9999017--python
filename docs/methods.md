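# Methods

This note documents the models, conventions and design choices behind
`stirqmri`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the phantom experiments do and do not show.

## Phantom cohorts

**What is emulated.** The generator reproduces the image *statistics*
that the downstream features consume, not anatomy or MR physics. On a
fat-suppressed STIR-like intensity scale (abstract 0–255-type units):

* healthy muscle pixels follow N(μ=100, σ=10), truncated at 0;
* residual (suppressed) fat follows N(mode=30, σ=8) — dark;
* edema follows N(180, 15) — bright;
* the subcutaneous-fat ring additionally contains ≤ 5% (default 4%)
  bright "vessel" pixels N(220, 15), which shift the ring's *mean*
  upward but leave its *mode* at the fat value — the reason the lower
  reference limit is defined as a mode.

Each subject is a stack of 2D slices (6 for controls, 3 for patients)
with a fixed, pre-aligned rectangular ROI layout: 6 muscles × 2 sides
(≈ 1.9 k pixels per ROI at the default 192×192 size; the layout scales
down to 64×64 keeping every ROI ≥ 64 pixels). Background carries low
|N(0, 2)| noise.

**Patient ROIs.** Per muscle and side, latent fractions f ~ U(0, 0.6)
(fat) and e ~ U(0, 0.3) (edema) are drawn with a Gaussian-copula
correlation of 0.8 between sides: sides are similar — as left/right
averaging assumes — but not identical. `round(f·n)` fat and `round(e·n)`
edema pixels are placed as 8-connected random-walk-grown patches
(15–120 px per patch); connected blobs keep size-zone statistics
non-degenerate, where salt-and-pepper placement would reduce every zone
to a single pixel.

**Ground-truth link.** Per muscle, with f̄, ē the left/right latent
means:

    FF  = 100 · f̄ + ε,   ε  ~ N(0, 3 pp),  clipped to [0, 100]
    wT2 = 30 + 25 · ē + ε′, ε′ ~ N(0, 1 ms)

The link is deliberately linear-plus-Gaussian so that parameter-recovery
has a closed-form yardstick: the best possible MAE is the noise floor
E|ε| = σ·√(2/π) ≈ 2.4 pp / 0.8 ms. The flip side is discussed under
*Limitations*.

Everything is driven by one `numpy` generator seeded from
`PhantomParams.seed`; identical parameters give bit-identical cohorts,
including their serialized NIfTI/CSV form.

## Preprocessing

Inter-subject harmonization maps every slice onto the mid-calf slice of
the first healthy control (sorted by id) by exact empirical-CDF
histogram matching (the `skimage.exposure.match_histograms` map). Exact
CDF matching was chosen over coarser quantile-landmark matching because
it is *exactly idempotent* — renormalizing a normalized cohort is a
no-op, so repeated preprocessing cannot drift — while remaining
rank-preserving and bounded by the reference range. Bias-field
correction is out of scope: a `pre_hook` accepts externally corrected
slices, and phantoms are generated bias-free. Phantom cohorts share the
generator's intensity scale by construction, so harmonization is
optional (`normalize: false`) for phantom runs and on by default
otherwise.

## Radiomic catalog (56 features)

The catalog is a LIFEx-compatible stand-in with the 25/26/5 split:
25 first-order, 26 second-order (7 GLCM + 11 GLZLM + 8 GLRLM), 5 shape;
the exact membership lives in `data/feature_catalog.json` so it can be
revised without code change. Conventions that change numbers:

* **Quantization** — G = 64 levels, LIFEx-style relative bounds:
  `level = 1 + floor(G·(x − min)/(max − min + 1))`, clipped to [1, G];
  constant ROIs map to level 1.
* **First order** — population (n) variance; type-7 (linear
  interpolation) quantiles; entropies and uniformity on the quantized
  histogram; skewness/kurtosis of a constant ROI defined as 0 (excess 0)
  so vectors stay finite.
* **GLCM** — distance 1, four 2D directions (0°, 45°, 90°, 135°),
  symmetric pairs; per-direction matrices normalized then averaged
  *before* feature computation. Correlation of a single-level
  (degenerate) matrix is defined as 0. Direction averaging makes the
  features invariant under 90° image rotation.
* **GLZLM** — 8-connected flat zones. Note that under 8-connectivity a
  checkerboard is *two* diagonal-linked zones, not sixteen singletons.
  Mass balance Σ(size × count) = ROI pixel count is asserted on every
  extraction.
* **GLRLM** — per-direction run matrices; features computed per
  direction and averaged, which keeps run percentage in (0, 1].
* **Shape** — in-plane perimeter is the boundary-edge count × pixel
  spacing (6 edges for a 2×1 rectangle); the slice is extruded to its
  thickness for volume (mL) and surface (mm²); sphericity and
  compactness use the extruded slab's total surface.

Left and right ROIs are computed independently and averaged
feature-wise; a missing side is logged and the available side used.

## Dimensionality reduction

**PCA (WF1)** — features are z-scored (training rows only), zero-variance
columns dropped with a warning, and 6 components retained (≈ 90% of the
variance on these tables).

**Information imbalance (WF2)** — Δ(A→B) = (2/N)·⟨rank_B(nn_A(i))⟩ with
Euclidean distances on z-scored columns; ranks start at 1 for the
nearest non-self neighbor. All ties (equal distances, tied nearest
neighbors) break by ascending point index — on discretized data the
estimate depends on this rule, so it is fixed and stable. Δ ∈ [2/N, ≈1];
it is invariant under affine rescaling of the target but *not* under
general monotone maps, which reorder 1-D pairwise distances. The subset
search is exhaustive at sizes 1–2 and greedy-forward (add the feature
minimizing Δ) up to `max_subset_size` (default 8) — chosen for
tractability and reproducibility over the 2^56 subset space; the
reported subset is the argmin over the size→Δ curve, which is written
out per muscle and target.

**Fit scope** — by default PCA and subset selection are refit inside
every training fold (`reduce.fit_scope: fold`), so no held-out subject
leaks into the transform; `global` fits once on all rows for comparison
with analyses that reduce before cross-validating.

## Reference limits and WF3

Healthy-control pixels are pooled per muscle over all subjects, sides
and slices (a `per_subject` switch averages per-subject μ + 2σ instead;
with ~10⁵-pixel pools the two differ negligibly, as does n vs n−1 in
σ). UL_i = pooled mean + 2·population SD. LL is the mode of the pooled
subcutaneous-fat histogram on integer-centered bins of width 1 intensity
unit (configurable); ties take the lowest bin. FFG/MEG use *strict*
inequalities (< LL, > UL) — boundary handling had to be fixed one way
and strictness is the conservative choice; both are computed per side
and averaged. On the default phantom, Spearman correlation between
latent f and FFG (and e vs MEG) exceeds 0.9 across 150 ROIs, the
construct-validity floor that makes WF3 informative.

## Models and evaluation

Seven regressors with fixed, logged hyperparameters (no tuning — the
comparison is between workflows, not hyperparameter searches):
KNN k=5 Euclidean; Ridge α=1.0; Lasso α=0.01; tree max depth 5; random
forest 100 seeded trees; SVR with RBF kernel, C=1, ε=0.1; plain linear
regression. Inputs are standardized with training-fold statistics only.

Cross-validation: seeded shuffle, 5 folds differing by ≤ 1 in size.
The mean MAE is the arithmetic mean over folds (a sum over 5 folds
would be 5× larger than the per-fold error scale and inconsistent with
calling it a mean); the parenthesized dispersion is the sample (k−1) SD
across folds. The fold shuffle seed is shared across workflows and
models within a run, so workflow contrasts are paired rather than
fold-lottery noise.

The coefficient of variation is population SD / mean; the correlation
screen reports Pearson and Spearman coefficients (two-sided p) of the
per-muscle KNN mean MAE against the CV of ground-truth FF, wT2 and
muscle volume, and against mean muscle volume.

## Problem sizes

Default study runs use the calibrated cohorts: 25 FSHD-like subjects
(seed 1234) and 6 controls (seed 7) at 192×192 pixels, ~1.9 k pixels per
muscle ROI, features on the mid-calf slice, limits on all six HC slices.
A full three-workflow run completes in a few minutes on one CPU; module
tests use 96×96 cohorts.

## Limitations

* **Linear link favors linear models.** Because ground truth is an
  affine function of the latent fractions and FFG/MEG are, up to
  counting noise, proportional to those fractions, linear regression is
  near-optimal on the phantom and outperforms KNN (measured on the
  default cohort: LR ≈ 2.4 pp vs KNN ≈ 4.0 pp muscle-averaged FF MAE).
  On real STIR data the intensity→biomarker relation is nonlinear and
  heteroscedastic, which is where neighborhood-based models can win;
  phantom results therefore validate the machinery and its error
  floors, not the real-data ranking of model families. Applying
  histogram matching to the phantoms (per-subject quantile warping, a
  genuinely nonlinear distortion) raises all models' errors
  (KNN ≈ 5.3, LR ≈ 4.4 pp) without changing that ordering.
* **Constant muscle volumes.** The fixed ROI layout makes every
  subject's muscle volume identical, so the volume-CV series is exactly
  zero and its correlation screen rows are undefined (reported as NaN).
  Real cohorts vary anatomically.
* No MR physics, bias fields, scanner noise models, 3D texture or
  realistic anatomy; intensities are abstract units.
* Left/right correlation (0.8), blob patch sizes (15–120 px) and the
  latent ranges f ≤ 0.6, e ≤ 0.3 are plausibility choices spanning
  mild-to-severe involvement, not fits to a cohort.
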