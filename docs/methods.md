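# Methods

This document records the model implemented by `shellrad`, the parameter
choices with their defaults and rationale, the scope of the synthetic
generator, the numerical conventions, and the known limitations.

## 1. Partitioning

Input: a 3D CT volume and one tumor centroid in physical (mm)
coordinates. The volume is resampled to isotropic 1 mm spacing (trilinear
for intensities, nearest-neighbor available for masks) before any
geometry; output grid size per axis is `round(extent / target)`.

A voxel belongs to shell *[r_lo, r_hi)* iff the Euclidean distance from
its center to the centroid satisfies `r_lo <= d < r_hi`. The default
intervals [0,3), [3,6), [6,9), [9,12), [12,15) mm are half-open, so the
five shells are pairwise disjoint and their union is exactly the 15 mm
ball — a property the test suite asserts against brute-force per-voxel
distance checks. Shells truncated by the volume boundary are a warning,
not an error (peripheral lesions). Partitions are cropped to the
`±r_max` cube around the centroid with non-member voxels set to the fill
value (−1024 HU, air).

## 2. Handcrafted features (1688 per partition)

`14 shape + 93 × 18 image variants = 1688`.

- **Shape (14)**: mesh volume and surface area from marching cubes on the
  padded mask, voxel volume, surface/volume ratio, sphericity, maximum 3D
  diameter (convex hull), three per-axis maximum 2D diameters, three
  principal-axis lengths (4√λ from the voxel-coordinate covariance
  eigenvalues), elongation, and flatness. Computed once per partition on
  the mask only.
- **Intensity/texture (93)** on each variant: 18 first-order, 24 GLCM,
  16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM. Gray levels are discretized with
  a **fixed bin width of 25 HU** anchored at the partition minimum
  (`level = floor((x − min)/25) + 1`); a fixed width keeps levels
  comparable across subjects with differing dynamic range. Texture
  matrices use 13 unique 3D directions at distance 1 (GLCM symmetric and
  averaged over directions; GLRLM averaged over directions; GLSZM zones
  are 26-connected; GLDM dependence uses α = 0; NGTDM neighborhood is the
  26-neighborhood mean).
- **Variants (18)**: original; 8 wavelet sub-bands (one-level separable
  `coif1`, reflect padding); Laplacian-of-Gaussian at σ = 1…5 mm
  (σ²-scaled); square, square root, logarithm, exponential remaps
  (max-normalized before remapping so the outputs stay bounded). Filters
  are applied to a bounding box grown by a 10-voxel margin so boundary
  effects do not reach the partition.

Degenerate partitions (< 2 voxels) and non-isotropic inputs are errors.

## 3. Polar slicing and deep features (256 per partition)

The partition's cube is resampled onto 36 full planes through the
centroid's z-axis, rotated in 10° steps over [0°, 360°) (the plane spans
both sides of the axis, so the slice at θ+180° is the left-right mirror
of the slice at θ — asserted exactly in the tests). Each slice is a fixed
224×224 nearest-neighbor sampling spanning [−r_max, r_max] in both the
radial and z directions, with symmetric pixel centers
`(j − (W−1)/2) · 2r/W`. Non-partition voxels take the fill value.

Slices are windowed to [−1024, 400] HU, min-max normalized to [0, 1], and
replicated to 3 channels. Each slice passes independently through a
frozen backbone: five 3×3 stride-2 convolution blocks (channels 16, 32,
64, 128, 256) with ReLU, He-initialized from a seeded RNG, mapping
224×224 → 7×7. Global average pooling over 7×7 gives a 256-vector per
slice (36×256 per partition); an elementwise maximum across slices gives
the final 256-vector. The max is permutation-invariant in slice order.
Random frozen weights stand in for a pretrained network so the pipeline
is reproducible offline; `load_backbone_weights` accepts external
weights with the same block structure.

## 4. Nine strategies, selection, and classification

| strategy | columns |
|---|---|
| shell_0_3 … shell_12_15 | 1688 each |
| feature_fusion | 5 × 1688 = 8440 |
| image_fusion (0–15 mm sphere) | 1688 |
| feature_fusion_integration | 8440 + 5 × 256 = 9720 |
| image_fusion_integration | 1688 + 256 = 1944 |

**Split.** One stratified train/test split (default ratio 0.2, seeded) is
shared by all strategies. Per-class test counts use largest-remainder
rounding of `count × ratio`, so class proportions are preserved within
one subject; e.g. a 175/151 cohort at 0.2 yields a 35/30 test set.

**LASSO selection.** The 0/1 label is regressed on z-scored features with
an L1 penalty over a descending grid of 100 log-spaced values from
λ_max = max|Xᵀy_c|/n (the smallest penalty that zeroes every coefficient)
down to 10⁻⁴·λ_max. Mean squared error is estimated by stratified,
seeded 10-fold CV; the first minimum on the descending grid is taken, so
ties break toward the larger penalty (sparser model). Constant columns
are dropped with a warning. Because `lasso_path` fits without an
intercept, fold labels are centered before fitting and the fold mean is
added back to predictions. If the selection is empty, the single feature
with the largest absolute label correlation is kept (with a warning) so
downstream training always has input. On orthonormal designs this
selection provably equals the soft-threshold rule
β_j = S((Xᵀy_c)_j / n, λ), which the tests verify.

**Classifier.** RBF SVM, C = 1, gamma = 'scale', features z-scored inside
the pipeline, Platt-calibrated probabilities. Out-of-fold probabilities
from seeded stratified 10-fold CV on the training cohort give the CV AUC
and the cutoff; the model is then refit on the full training cohort. The
fold count is clamped to the minority-class size when needed.

## 5. Evaluation

- **AUC** is the midrank Mann–Whitney statistic (ties get half credit) —
  identical to brute-force concordant-pair counting.
- **Variance/CI** use the DeLong structural components: per-positive
  V10 and per-negative V01 from midranks; the 95% CI is
  AUC ± 1.96·√(S10/m + S01/n), clipped to [0, 1].
- **Paired DeLong test** between two strategies' scores on the same test
  subjects uses the 2×2 component covariance; z = ΔAUC/√var, two-sided
  normal p. If the variance of the difference is ≤ 10⁻¹⁶ (e.g. identical
  or monotone-transformed scores), p = 1 when ΔAUC ≈ 0. The tests compare
  this against a 10⁴-draw permutation oracle that swaps the two scores
  within subjects — the exchangeability null for paired AUCs.
- **Cutoff**: maximizes Youden's J = sensitivity + specificity − 1 over
  the training CV scores' candidate thresholds (midpoints between
  adjacent unique scores plus sentinels); ties break toward the lower
  threshold. Predicted positive is `score ≥ cutoff`.
- **Metrics**: accuracy, sensitivity, specificity, precision, F1 from the
  confusion matrix; reported values are rounded half-up to 2 decimals via
  `decimal.Decimal` (bankers' rounding would corrupt .x25 boundaries).
  Zero predicted positives yields precision 0 with a warning.
- **Decision-curve analysis** for the fusion/integration strategies: net
  benefit NB(p_t) = TP/n − FP/n · p_t/(1−p_t) over p_t ∈ {0.01…0.99},
  with treat-all and treat-none references.

## 6. Synthetic phantom generator

The generator's defaults are the study conditions for all statistical
acceptance checks; they were fixed before those checks were run and are
not tuned to outcomes.

Each subject is a 64³ volume at 1 mm: air background (−1024 HU), a
soft-tissue ball (−100 HU, radius 26 mm) with i.i.d. N(0, 20²) HU noise,
and a quasi-spherical tumor (40 HU) whose radius is drawn uniformly from
8–14 mm and whose boundary is perturbed by a smooth random field
(±1.5 mm) so shells genuinely mix intratumoral and peritumoral voxels.
The centroid annotation is jittered by up to ±0.4 mm per axis. For the
"response" class only, voxels whose centroid distance falls in the signal
band ([9,12) mm by default) receive additional band-limited texture:
smoothed (σ = 1.5 voxels) unit-variance Gaussian noise scaled by the
effect amplitude (60 HU by default) — a heterogeneity contrast of the
kind run-length/dependence features detect. The texture field is drawn
for every subject regardless of label so that effect = 0 makes the two
classes bitwise-identically constructed (asserted in tests). Subjects are
generated from `SeedSequence(seed).spawn(...)` children, so cohorts are
bitwise reproducible and subjects statistically independent.

Scope: the phantoms test *pipeline correctness and signal localization*,
not clinical realism — no scanner physics, anatomy, or partial-volume
modeling. Cohort sizes (2×40 for acceptance, 2×12 in examples/tests) are
the package's own desk-scale choices; clinical-scale AUC magnitudes on
real cohorts are out of scope and not claimed.

## 7. Statistical acceptance properties

- **Localization**: over 10 seeded 2×40 cohorts at the default operating
  point, the shell_9_12 model must attain the top mean CV AUC among the
  five shell models in ≥ 8 seeds (run with the reduced, original-variant
  handcrafted config for runtime).
- **Null calibration**: at effect = 0, one full nine-strategy run's test
  AUCs must all lie in 0.5 ± 0.35. With an 8/8 test split the null AUC
  standard deviation is √((m+n+1)/(12mn)) ≈ 0.15, so ±0.35 is ≈ 2.35 sd;
  even treating the nine correlated strategies as independent, the
  chance of any excursion beyond the band is ≈ 9 × 0.019 ≈ 0.17 as an
  upper bound, and far smaller in practice given the strong positive
  correlation between strategies sharing one test set. The run is seeded,
  so the check is deterministic.

## 8. Numerical conventions

- First-order moments are population (ddof = 0) moments; skewness and
  kurtosis are 0 for constant regions.
- GLCM MCC uses the eigenvalues of the Q matrix with a guard for
  degenerate (single-level) regions; NGTDM coarseness is capped at 10⁶.
- Histogram entropy uses log₂ with 0·log 0 = 0.
- Float32 is used inside the conv backbone (weights and activations);
  everything else is float64.
- All RNG is `numpy.random.default_rng` / `SeedSequence`; no global seeds.

## 9. Limitations

- The handcrafted bank follows standard image-biomarker formulas but is
  an independent implementation; values are validated against in-repo
  brute-force oracles, not against any external package's output.
- The deep backbone is frozen and randomly initialized by default;
  features are reproducible but carry no pretrained semantics.
- LASSO-on-0/1-labels is a linear-probability surrogate used for
  selection only, not a calibrated model.
- DeLong p-values are asymptotic; at very small test sets (examples) they
  are indicative only.
- The generator plants a variance/heterogeneity contrast; signals that
  alter only mean intensity or shape are outside the planted-signal
  acceptance property (though the features would respond to them).
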