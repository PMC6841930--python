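# Methods

`toothmark` implements a landmark-based pipeline for discriminating the
canid (wolf / dog / fox) that produced a tooth mark on bone, combining
geometric morphometrics with an RBF-kernel SVM classification protocol, plus
a synthetic data generator that reproduces the statistical structure of an
experimental reference collection.

## Landmark models

Two fixed landmark schemes are used:

* **Scores** (elongated grooves): a 7-landmark 2D model of the transverse
  cross-section. Landmarks 1 and 7 mark the groove edges on the bone
  surface, landmark 4 the deepest point, landmarks 2/6 the walls at half
  maximal depth and 3/5 at three-quarter depth, ordered left to right.
* **Pits** (sub-circular depressions): a 17-landmark 3D model — 8 landmarks
  on the crater rim, 8 on the walls at half depth, 1 at the deepest point.

From the score model the seven classical groove measurements are computed:
widths at the surface, half depth and three-quarter depth (WIS, WIM, WIB),
the maximal depth D (perpendicular to the surface chord LM1–LM7, not
vertical), the opening angle OA at the deepest point, and the two wall
angles LWA, RWA. Note OA + LWA + RWA = 180° exactly (they are the angles of
the triangle LM1–LM4–LM7), so the seven raw columns are rank-deficient by
one; analyses either run PCA first or drop OA. All seven are invariant to
rigid motions; lengths are homogeneous of degree one under scaling and
angles invariant.

## Superimposition and shape/form spaces

Generalized Procrustes Analysis removes translation (centering), size
(scaling to unit centroid size, CS = root summed squared distances from the
centroid) and orientation (iterative rotation to the running consensus,
rotations only — tooth marks are chiral, so reflections are never allowed).
Convergence is declared when the consensus moves less than 1e-10 in
Frobenius norm (default cap 100 iterations); the per-iteration summed
squared residual trace is stored and is non-increasing.

Two post-processing conventions matter and are deliberate:

* **Orientation pinning.** GPA determines the aligned sample only up to one
  global rotation. The consensus is rotated onto its principal axes with a
  deterministic sign rule and the whole sample follows. This makes the
  output invariant (to ~1e-12) to arbitrary similarity transforms applied
  to the raw data, and makes repeated runs comparable coordinate by
  coordinate.
* **Tangent projection.** Aligned shapes are mapped into the linear space
  tangent to the unit sphere at the consensus by the projective (gnomonic)
  map x → x/(x·c). This satisfies the same linear constraints as the
  orthogonal-subtraction variant — so the shape-space dimension bookkeeping
  below is identical — but has the additional property that re-normalizing
  the projected shapes recovers the spherical shapes exactly, which makes
  the whole GPA map idempotent to machine precision (re-running GPA on its
  own output is a no-op). The cost is that projected configurations have
  centroid size 1 only to second order in the Procrustes radius.

The dimension bookkeeping follows from the constraints: centering removes
d, the unit-size/tangent constraint 1, and rotation alignment d(d−1)/2
dimensions, so shape variation spans kd − d − d(d−1)/2 − 1 dimensions — 10
for the 7×2 score model and 44 for the 17×3 pit model. `count_pc_scores`
reports these as the count of PCA eigenvalues above 1e-10 of the largest.

**Form space** retains size by multiplying each specimen's flattened
aligned coordinates by the natural log of its centroid size, keeping all
k·d coordinate columns (14 for scores, 51 for pits). Coordinates are
interpreted as millimetres and CS is converted to micrometres
(`unit_scale=1000`) before the log so that ln CS is always positive and
monotone in size; any rescaled CS ≤ 1 is rejected with instructions to
change units. Form-space PCA reports all min(n−1, kd) score columns, since
the log-size rescaling leaves no structurally-zero directions. The
alternative convention — appending ln CS as a single extra column — is
deliberately not used because it yields kd+1 columns, not kd; the
construction is isolated in `to_form_space` so it can be swapped.

Thin-plate splines (kernel r² ln r² in 2D, −r in 3D) provide the
deformation grids used to visualize shape extremes along principal
components; the spline maps reference landmarks onto targets exactly and
its bending energy (the quadratic form of the non-affine part) vanishes for
affine deformations.

## Synthetic study sample

The generator emulates a reference collection of marks from feeding
experiments, with the reference sample sizes: pits fox 29 / wolf 24 /
dog 30 (83) and scores fox 41 / wolf 30 / dog 34 (105). Class signal is
placed in three channels, matching the qualitative findings for real marks:

| parameter | wolf | dog | fox | emulates |
|---|---|---|---|---|
| size scale (mm; score width / pit diameter) | 3.0 | 2.0 | 1.2 | wolves leave the largest marks |
| depth/width ratio | 0.30 | 0.45 | 0.60 | foxes leave relatively deeper marks |
| landmark noise (fraction of CS) | 0.025 | 0.020 | 0.015 | wolves are the most variable |

Each specimen is its class template plus isotropic Gaussian landmark noise
and a log-normal whole-mark size factor (σ = 0.1). `separation` scales
every between-class template difference around the across-class mean;
at 0 the classes are indistinguishable by construction (used for null
calibration). The default separation (2.0) is the one calibrated constant:
it is set so that the default sample is fully separable under the complete
classification protocol, *mirroring* the empirically perfect classification
reported for real marks — passing tests on this fixture demonstrates the
pipeline, not the biology. Real marks differ in ways the generator does not
model: anisotropic and spatially correlated digitizing error, bone-surface
curvature, within-individual tooth differences, and non-Gaussian size
distributions.

## Statistics

PCA is covariance PCA on column-centred data. Pairwise MANOVA (dog vs wolf
and dog vs fox, per data view) runs on variance-ordered score columns
truncated to ≥ 95 % cumulative variance, with at least 2 and at most
n₁ + n₂ − 3 (and min(n₁, n₂) − 1) columns so the error degrees of freedom
stay positive and covariances invertible. Box's M (chi-square
approximation, α = 0.05) gates the statistic: Hotelling-Lawley trace for
homogeneous covariances, Wilks' Λ otherwise. In the two-group case both
reduce to Hotelling's T², so the gate changes the label, not the inference;
the F approximations are exact there and the test is calibrated (type-I
error ≈ 0.05 under a simulated null).

## Classification protocol

Per data view — measurements with OA (7 columns), without OA (6), score
shape-space PCs (10), pit form-space PCs (51) —:

1. **Split** 70:30, stratified by class, on the original specimens.
2. **Bootstrap** the training partition (stratified, within-class, with
   replacement) to 700 rows (70 % of the nominal 1000-row augmented size).
   The alternative order — bootstrap the pooled sample to 1000 and split
   afterwards — is available as `bootstrap_first=True`; it places duplicates of
   the same specimen on both sides of the split and inflates test accuracy,
   so the leak-free order is the default.
3. **Standardize** the measurement views to training mean/SD (the
   conventional treatment for heterogeneous-unit features, and the default
   behaviour of R's `e1071` SVM implementation); otherwise the
   degree-scaled angle columns dominate the kernel distance. PC-score views
   are *not* standardized: their columns are already commensurate and
   variance-ordered, and rescaling the trailing near-zero-variance
   components would amplify numerical noise into dominant features.
4. **Random search**, 50 draws of (cost, gamma) log-uniform on
   [1e-2, 1e3]², each scored by mean balanced accuracy over stratified
   10-fold CV with folds grouped by source specimen, so bootstrap copies of
   one specimen never straddle a fold boundary (without grouping, a
   memorizing kernel with gamma ~ 300 scores a perfect CV and collapses to
   chance on held-out data). Ties on the CV score — common on separable
   data, where dozens of draws reach a perfect score — are broken toward
   the smoothest boundary (smallest gamma, then smallest cost), a
   deterministic preference for the solutions that generalize over those
   that merely memorize.
5. **Train** the one-vs-one soft-margin RBF SVM and **evaluate** on the
   untouched 30 %: confusion matrix, Cohen's κ, macro sensitivity and
   specificity, balanced accuracy, exact Clopper–Pearson 95 % CI on the
   proportion correct, and a global MSE from per-item errors E = i − x on
   alphabetically integer-encoded labels (dog 0, fox 1, wolf 2). On a
   perfectly classified test set this MSE is exactly 0 by construction.
   Training time can be microbenchmarked (mean of 200 fits, ms); it is
   hardware-dependent and only reported.

All randomness derives from a single top-level seed; a full protocol run is
byte-identical across re-runs.

## Numerical notes and limitations

* GPA raises after 100 non-convergent iterations (never observed on
  non-degenerate data; typical convergence in ≤ 10 iterations).
* TPS systems with collinear/coplanar reference landmarks are singular and
  rejected with advice to jitter.
* The degenerate MANOVA case of exactly identical group means (zero
  hypothesis SSP) is returned as an exact null (p = 1).
* Measurement validation enforces positive widths/depth and OA ∈ (0, 180)°.
* Sample sizes throughout are the reference-collection sizes (83/105); the
  protocol's bootstrap augmentation (1000) and search budget (50 × 10-fold)
  match the reference protocol, and a complete four-view run takes on the
  order of a minute on one CPU.
* The generator's isotropic noise is a stand-in for the unknown within-class
  covariance of real marks; conclusions about real-data separability cannot
  be drawn from the synthetic fixture.
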