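# ctdem — CT differential-elasticity-map radiomics

`ctdem` turns a contrast CT volume and a lymph-node segmentation mask into a
**Differential Elasticity Map (DEM)** — a per-voxel, affine-invariant scalar
response intended to reflect local tissue elastic behaviour rather than raw
attenuation — and extracts the "mechanical texture" features that have been
used to predict nodal metastasis in oesophageal squamous cell carcinoma:
first-order entropy, multi-scale box-counting fractal dimensions, and
implicit-surface curvature descriptors. A statsmodels-style evaluation layer
then scores each feature diagnostically: group tests, ROC/AUC with Youden
operating points, DeLong comparisons, Hosmer–Lemeshow calibration and
decision-curve net benefit.

It is aimed at imaging researchers who want a transparent, fully testable
re-implementation of this analysis: every stage runs on synthetic phantoms
with known ground truth, so no clinical data are needed to exercise or audit
the pipeline.

## The model

After resampling to 1 mm isotropic voxels and light Gaussian smoothing
(σ = 1 voxel), Gaussian-derivative filters give the intensity gradient
∇I and Hessian H at every voxel. Under the assumption that soft tissue
deforms locally in an approximately affine way, the scalar elasticity
response is

```
E = ∇Iᵀ (H + εI)⁻¹ ∇I  =  trace((H + εI)⁻¹ ∇I∇Iᵀ)
```

which is exactly invariant to invertible linear coordinate changes
(g → Aᵀg, H → AᵀHA cancel) and to intensity offsets. ε is a small,
scale-aware regulariser (1e-3 × the largest Hessian eigenvalue magnitude in
the ROI) applied as a sign-preserving magnitude shift of the eigenvalues so
the response stays bounded where the second-order structure is weak. |E| is
compressed with a square root and min–max rescaled to [0, 255] inside the
padded node mask.

From the DEM within the mask:

- **entropy** — Shannon entropy (bits) of the value histogram (bin width 25);
- **fractal dimensions** — 3D box counting on super-level sets of the DEM at
  fixed levels of the [0, 255] range: occupancy counts at box sizes
  1, 2, 4, … averaged over seeded cyclic offsets, an OLS line fitted on the
  log–log curve over the scale window with the best adjusted R², and
  fd = −slope; the per-level dimensions are aggregated as
  max / best / average / median / min;
- **curvature** — Gaussian/mean/principal curvatures of the implicit
  isosurfaces, with shape index, curvedness, sharpness and total curvature.

## Worked example

```python
from ctdem import (CohortSpec, FeatureDiagnostics, RunConfig,
                   make_cohort, run_pipeline)
from ctdem.features import TABLE2_FEATURES

# synthetic two-class cohort: 30 metastatic-like + 30 benign-like phantoms
lesions, manifest = make_cohort(CohortSpec(n_pos=30, n_neg=30, master_seed=7))
manifest["volume"] = [l[0] for l in lesions]
manifest["mask"] = [l[1] for l in lesions]

result = run_pipeline(manifest, RunConfig())          # DEM + features + report
model = FeatureDiagnostics(result.features.drop(columns="case_id"),
                           features=list(TABLE2_FEATURES))
print(model.fit().summary())
```

```
Feature diagnostic evaluation
================================================================
lesions: 60  (label=0: 30, label=1: 30)
selection: p <= 0.05, oriented AUC > 0.7 -> 4/5 retained

feature                                       p    AUC         thr    ACC     Se     Sp     F1   HL p
-----------------------------------------------------------------------------------------------------
E_original_firstorder_Entropy            <0.001  0.882      0.6229  0.800  0.900  0.700  0.818  0.650
max_FD_feature                           <0.001  0.813       1.859  0.767  1.000  0.533  0.811  0.249
average_FD_feature                       <0.001  0.860       1.242  0.833  1.000  0.667  0.857  0.005
median_FD_feature                        <0.001  0.911       1.375  0.850  0.967  0.733  0.866  0.446

not retained: best_FD_feature

threshold rule: Youden's J on observed score midpoints
```

Reading the table: the DEM entropy of the heterogeneous (metastatic-like)
phantoms separates the classes with AUC 0.88; at the Youden threshold of
0.62 bits it classifies 80% of lesions correctly with sensitivity 0.90 and
specificity 0.70, and its probability calibration passes the
Hosmer–Lemeshow test (p = 0.65). The fractal-dimension aggregates are
systematically higher in the heterogeneous class, mirroring the elevated
multi-scale irregularity the features are designed to capture.

A command-line interface covers the same stages on NIfTI files:

```
ctdem synth --out cohort/ --n-pos 30 --n-neg 30 --seed 7
ctdem run --manifest cohort/manifest.csv --out results/
ctdem dem --volume ct.nii.gz --mask node.nii.gz --out dem.nii.gz
```

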