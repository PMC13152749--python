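# Methods

This note documents the models, estimators and numerical conventions behind
`ctdem`, the design choices that were genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Differential elasticity map

**Model.** The DEM treats the smoothed CT intensity I as a potential whose
local second-order geometry encodes tissue stiffness contrast. With gradient
g = ∇I and Hessian H (both from Gaussian-derivative filters), the response

E = gᵀ (H + εI)⁻¹ g

is invariant under invertible linear reparameterisations of space
(g' = Aᵀg, H' = AᵀHA give g'ᵀH'⁻¹g' = gᵀH⁻¹g) and under intensity offsets.
The assumption being exploited is that soft tissue deforms locally in an
approximately affine way, so E reflects intrinsic micro-structure rather
than acquisition geometry (slice thickness, reconstruction grid).

**Processing chain.** resample to 1 mm isotropic (trilinear; masks
nearest-neighbour, re-binarised at 0.5) → crop the node with a 4-voxel pad
(so σ = 1 filters have support beyond the boundary) → Gaussian smoothing
σ = 1 voxel → derivative fields → E → |E|^0.5 → min–max rescale to [0, 255]
using statistics from the padded mask only (background would otherwise set
the range). After 1 mm resampling, voxel units and millimetres coincide;
all filter scales are stated in voxels.

**Derivative filters.** Separable sampled derivative-of-Gaussian kernels,
reflect boundary, truncated at 6σ (the default 4σ truncation leaves ~0.5%
error in second derivatives of smooth fields). The kernels are
moment-corrected: the order-2 kernel is adjusted to annihilate constants and
ramps exactly and to reproduce the second derivative of a parabola exactly.
Without this, the raw sampled kernels' residual mass (~1e-6) couples the
Hessian to the absolute intensity level, breaking offset invariance
measurably once intensities reach CT magnitudes.

**Regularisation.** H is generically indefinite inside textured tissue, so
(H + εI) with a plain eigenvalue shift λ → λ + ε is singular wherever
λ = −ε, which sprays unbounded spikes across the map and makes the min–max
rescale meaningless (in practice the response spanned five decades and the
histogram collapsed into one bin). The implementation therefore uses the
sign-preserving magnitude shift λ → sign(λ)(|λ| + ε): identical for
positive semi-definite H, the same ε → 0 limit, and a response bounded by
|g|²/ε. ε defaults to 1e-3 × the largest |eigenvalue| of H over the ROI
(floor 1e-6), making the regularisation scale-aware. The signed response
can still be negative (indefinite H); its magnitude is used — the strength
of the elastic response — and the negative fraction is logged per lesion.

**Conventions.** Constant ROIs produce an all-zero DEM (a constant
compressed map has no range; zero is the documented convention).
Normalisation is per-lesion; entropy therefore measures the *shape* of each
lesion's response distribution, not its absolute scale, and DEM values are
not comparable across lesions in absolute terms.

## Features

**First-order.** Histogram features of masked DEM values. Entropy uses a
fixed bin width of 25 on the [0, 255] scale (≈10 bins), the usual
width-based discretisation of first-order radiomics extractors; this caps
entropy near 3.3 bits, so reported entropies are lower than pipelines using
finer bins, without affecting discrimination. Bin count mode is available.

**Box-counting fractal dimension.** For a binary voxel set: occupancy
counts N(s) at box sizes s = 1, 2, 4, … up to the set's largest extent,
each averaged over 8 seeded pseudo-random grid offsets; OLS fit of log N on
log s over every contiguous window of ≥ 3 scales (and ≥ 3 distinct counts);
the reported dimension is −slope of the window with the highest adjusted
R², ties broken toward longer windows, then finer scales. Offsets are
applied **cyclically** (the set is shifted modulo its bounding box padded to
a multiple of s). A non-wrapped offset grid inflates the expected count by
roughly (1 + s/L) per axis, which biases even a solid cube from dimension
3.0 to ≈2.84; cyclic offsets leave exactly self-similar sets (cube, plane,
line) with their ideal counts at every offset while still averaging out
alignment luck on irregular sets. Sets below 8 voxels are flagged
unreliable. A per-slice 2D mode is available behind a flag.

*Known limitation*: a digitised level-3 Menger sponge (27³) measures
≈2.4–2.6 rather than its limit dimension log20/log3 ≈ 2.727, because
power-of-2 box grids never align with base-3 self-similarity and only five
octaves exist at that lattice size; with power-of-3 scales the same counts
recover 2.727 exactly. This is a property of the estimator family (base-2
scale vector), not of the implementation.

**FD feature aggregates.** The multi-level substrate is the family of
super-level sets {DEM ≥ t} ∩ mask at fixed levels t = 25.5, 51, …, 229.5
(deciles of the output range). Fixed absolute levels matter: sets at
*value-percentile* thresholds contain a fixed fraction of mask voxels by
construction, so their dimension barely responds to how widely the
elasticity response is spread — empirically the class signal vanished
(AUC ≈ 0.5). With fixed levels, lesions whose response spreads far up the
range populate more levels with denser, more space-filling sets, raising
the aggregates; the resulting dimensions (~1.2–2.3) also sit in the range
reported for this feature family in the clinical setting. Aggregates:
max / average / median / min over levels, plus `best_FD_feature` — the
dimension at the level whose fitting window attains the globally highest
adjusted R². Degenerate (constant) maps fall back to a single whole-mask
level.

**Curvature.** Each masked voxel is treated as lying on the DEM isosurface
through it. Gaussian curvature K = gᵀadj(H)g / |g|⁴ and mean curvature
H_c = (gᵀHg − |g|² tr H) / (2|g|³) give principal curvatures
κ₁,₂ = H_c ± √max(H_c²−K, 0). The sign convention follows the map's
gradient orientation: a spherical distance field has κ₁ = κ₂ = −1/r and
K = 1/r². Derived: shape index (2/π)·atan((κ₁+κ₂)/(κ₁−κ₂)) with flat
umbilics mapped to 0 and curved umbilics to sign(H_c); curvedness
√((κ₁²+κ₂²)/2); sharpness κ₁−κ₂; total curvature Σ|K|. Voxels with
|g| below 1e-6 × the ROI maximum have no defined isosurface normal and are
excluded; an all-excluded ROI (e.g. constant DEM) yields NaN summaries with
a flag rather than zeros.

## Statistical evaluation

- **Group comparison** routes continuous features to the pooled-variance
  t-test when both groups pass Shapiro–Wilk normality and Levene
  homogeneity at α = 0.05, otherwise to the Mann–Whitney U test; constant
  data returns p = 1 with a degenerate flag. Contingency tables use the
  chi-square test (Yates-corrected for 2×2) or Fisher's exact test for 2×2
  tables with an expected cell below 5.
- **Selection** keeps features with p ≤ 0.05 *and* orientation-free AUC
  max(AUC, 1−AUC) > 0.7. No multiple-testing correction is applied — the
  two-stage filter is used as published — which is a known limitation.
- **AUC** is the tie-corrected rank statistic P(s⁺ > s⁻) + ½P(tie),
  identical to the trapezoidal area under the empirical ROC.
- **Operating points** maximise Youden's J over midpoints of consecutive
  distinct scores (rule: score ≥ threshold → positive; ties resolve to the
  lowest threshold). The published tables never state their threshold rule;
  Youden's J is assumed and reported as such. Negatively oriented features
  are negated before thresholding so the reported threshold lives on the
  oriented scale.
- **DeLong** uses placement values with the standard covariance estimate;
  a zero-variance difference returns p = 1 with a flag. Calibration under
  the null was verified by simulation (rejection rate ≈ 0.05 at α = 0.05).
- **Hosmer–Lemeshow** bins by predicted-probability deciles (ties kept
  together; degenerate bins merged and flagged) with the χ² on g−2 degrees
  of freedom. The g−2 convention is the regression-calibration standard and
  is slightly anticonservative when probabilities are known to be true, as
  in simulation tests.
- **Decision curves** report NB(p_t) = tp/n − (fp/n)·p_t/(1−p_t) on a
  0.01-step grid against treat-all and treat-none references, displayed by
  default over 0.10–0.70, the clinically quoted range.
- **Probability link**: a univariate maximum-likelihood logistic model maps
  one feature to class probability for calibration and decision-curve
  analysis; perfect separation is caught, flagged, and probabilities are
  clipped away from {0, 1}.
- Confusion matrices can be reconstructed from printed
  sensitivity/specificity with round-half-up counts; this reproduces the
  published accuracy/PPV/NPV/F1 of every operating-point row to ±0.001,
  an internal-consistency check of those tables.

## Synthetic data

The generator provides every input class the pipeline needs:

- **Quadratic oracle fields** I(x) = xᵀMx + bᵀx + c with exact gradient
  2Mx + b and Hessian 2M, for verifying the response formula, its affine
  invariance, and the filters.
- **Canonical fractal sets** (cube, plane, line, Menger sponge) with known
  limit dimensions.
- **Lesion phantoms**: an ellipsoidal node (default semi-axes 9×10×11
  voxels ≈ 2 cm, jittered per lesion) at 45 HU embedded in soft-tissue
  background (25 HU, 5 HU white noise) on a 48³ grid at 1 mm. Interior
  texture is a sum of unit-variance Gaussian random fields (white noise
  smoothed at the component's correlation length): the benign-like class
  has one smooth, weak component (correlation 4 voxels, amplitude 2.5 HU);
  the metastatic-like class mixes three scales (1/2/4 voxels at 16/12/10 HU),
  emulating the patchy, multi-scale architecture of infiltrated nodes.
  These defaults were fixed once so that the two classes separate in the
  published regime (entropy AUC ≈ 0.85–0.93 on 30+30 cohorts across master
  seeds, all four FD aggregates higher in the heterogeneous class).
- **Covariate tables** with the published baseline contingency structure,
  for exercising the categorical tests.

What the phantoms do *not* emulate: CT physics (beam hardening, dose-
dependent noise correlation), anatomical context (vessels, adjacent nodes),
segmentation error, or scanner/protocol heterogeneity. Passing the
synthetic recovery test shows the pipeline detects multi-scale texture
contrast of the designed kind at realistic node sizes — it does not certify
clinical performance. A high lesion/background contrast (e.g. a node in
pure fat at −80 HU) makes the boundary-edge response dominate the map by
orders of magnitude; interpreting DEM histogram features in such settings
would require boundary handling beyond what the published processing chain
specifies.

## Numerical conventions and edge cases

- Dice of two empty masks is 1.0 (documented convention).
- ROI pad default 4 voxels; the pad region feeds filter support and the
  normalisation statistics mask (mask dilated by the pad).
- Both-endpoint attainment of [0, 255] holds within the padded stats mask;
  outside it values are zeroed.
- Seeds: box-counting offsets derive per-level streams from a
  `SeedSequence`; cohort generation derives per-lesion seeds from a master
  seed; everything else is deterministic.
- Undefined rates (zero denominators) are NaN, never silently 0.

## Problem sizes used in the test suite

Phantoms are 48³ voxels with ~4–5k-voxel masks; cohorts are 30+30 lesions;
DeLong null calibration uses 500 replicates of n = 200; the AUC oracle
comparison uses 200 random instances. These sizes were chosen so the full
suite and the acceptance script each complete in minutes on a single CPU
while keeping every stochastic check well-powered.
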