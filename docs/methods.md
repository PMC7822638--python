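# Methods

## Model and assumptions

A subject is a single-slice cine sequence, stored as a third-order tensor
X ∈ ℝ^{I×J×K} (rows × columns × cardiac phases). The classification model
is linear end to end:

    score(X) = ⟨W, X − M⟩ + b,

where M is the training-mean tensor and W is constrained to a sum of at
most S rank-one eigentensors learnt by multilinear PCA (MPCA). The
pipeline assumes (i) all subjects can be brought into a common frame by a
2-D similarity transform (translation, rotation, isotropic scale,
optional reflection) — i.e. one imaging plane, no through-plane motion or
deformable anatomy differences beyond what the classifier should learn;
(ii) the discriminative signal survives spatial downsampling; and
(iii) a linear decision boundary in MPCA feature space is adequate. The
design deliberately prefers a small number of strongly regularised,
interpretable components over flexible nonlinear models, because the
intended regime is ~10²  subjects against ~10⁴–10⁵ voxels.

### MPCA

Fitting alternates over modes. With centred samples, each mode k is
initialised from the eigenvectors of its full mode-k scatter matrix, and
the mode dimension d_k is fixed there as the smallest count whose
eigenvalue mass reaches the per-mode variance threshold (default 0.97).
Each sweep then re-solves mode k's eigenproblem on the partial scatter of
samples projected through the other two modes' current bases. The
captured variation Ψ (sum of retained eigenvalues = total squared norm of
the projected samples) is non-decreasing across updates; iteration stops
when its relative improvement falls below `tol` (1e-6) or after
`max_iter` (10) sweeps — MPCA converges in a handful of sweeps in
practice, and the cap keeps runtime deterministic. Eigenvectors are
sign-fixed (largest-magnitude entry positive) so repeated fits and the
derived feature maps are bit-reproducible. Feature tensors flatten
row-major over (p, q, r); the order is recorded in the serialised model.

### Feature selection and classifiers

Features are ranked by the two-class Fisher ratio
F = (μ₁ − μ₀)² / (σ₁² + σ₀² + ε) with unbiased class variances and
ε = 1e-12 guarding zero-variance features; ties rank the lower flat index
first. The retained count S is chosen by stratified 10-fold CV on the
training split only, scoring mean held-out AUC of the designated
classifier over the candidate grid {1, 2, 5, 10, 20, 50, 100, 200, all}
(intersected with the feature count — a log-spaced grid bracketing the
tens-of-features regime this model family typically selects); ties take
the smallest S. Classifiers are sklearn's linear-kernel SVC and
LogisticRegression, both at regularisation constant C = 1.0 by default.
Features are standardised on the training fold and the standardisation is
folded back into (β, b), so stored weights act on raw feature units;
class 1 (disease) is the positive score direction, which makes positive
feature-map voxels "red"/disease by convention.

### Evaluation

Outer evaluation is stratified 10-fold CV with *everything* — mean
tensor, projections, ranking, S, standardisation, classifier — refitted
inside each training split; held-out folds are only scored (the test
suite checks this by corrupting held-out data and asserting no fitted
parameter moves). The headline number is the mean of per-fold AUCs;
pooled held-out scores are kept because the equal-sensitivity–specificity
operating point is only meaningful on pooled scores. The operating point
scans midpoints between adjacent distinct scores (plus sentinels),
minimises |sens − spec| with ties going to the higher common value and
then the lower threshold, and reports accuracy as (sens + spec)/2 — equal
to the common value whenever the discrete ROC allows exact equality —
plus PPV and NPV from the confusion counts.

AUC uses the trapezoidal/midrank convention (sklearn's
`roc_auc_score`); the test suite keeps an independent brute-force
pair-counting oracle at tolerance 1e-12. Confidence intervals for AUC are
deliberately out of scope.

## Preprocessing choices

- **Coordinates**: 0-based pixel coordinates, x = column, y = row, origin
  top-left; all landmark files use this convention.
- **Registration**: closed-form Procrustes (centroid alignment, scale
  from the trace identity, rotation from the 2×2 cross-covariance SVD);
  both det = ±1 branches are solved and the reflection is kept only when
  it strictly lowers the residual. The fit recovers any transform of its
  own family exactly (< 1e-6 px) from noise-free landmarks. Warping is
  bilinear with zeros outside the field; QA flags a subject when the
  maximum landmark residual exceeds 20 px on a 512 grid (scaled
  proportionally at other grids) — configurable.
- **Masking**: five boundary points determine the conic exactly (5
  equations, 6 homogeneous unknowns), so exact interpolation is used
  rather than least squares; non-elliptical or non-unique conics raise.
  The "large" variant dilates the fitted ellipse about its centre by a
  configurable factor, default 1.5 — the small/large geometric
  relationship is not externally constrained, so it is exposed rather
  than hard-coded.
- **Rescaling**: exact block averaging when the target divides the
  source, area-weighted anti-aliased resampling otherwise; the frame
  count K is never resampled. Pixel spacing is recomputed as field of
  view / target; with the 480 mm FOV used throughout, grids 32/64/128/512
  give 15/7.50/3.75/0.9375 mm (note 480/256 = 1.875 mm exactly, and
  480/512 = 0.9375 prints as 0.94 at two decimals).

## The phantom: what it emulates and what it does not

The synthetic cohort emulates the *structure* of a two-class short-axis
cine dataset, not its appearance. Geometry (all lengths as fractions of
the image side L): LV = disc at (+0.10 L, 0) from centre, epicardial
radius 0.17 L with a 0.05 L wall that thickens in systole; RV = crescent
formed by a 0.21 L disc at (−0.08 L, 0) overpainted by the LV, sharing
the septal wall; intensities background 0.15, myocardium 0.45, blood
0.75 (range [0.15, 0.75] before noise, clipped to [0, 1] after).
Contraction is sin²(πt/(K−1)) — smooth, periodic, end-systole at
mid-cycle — so temporal features are recoverable at end-systole.

Disease effects, both scaled by `effect_size` ∈ [0, 1]:

1. septal bowing: the LV boundary radius is reduced by a Gaussian angular
   bump (amplitude 0.18·effect, width 0.6 rad) centred on the direction
   facing the RV;
2. contraction deficit: the RV radial contraction amplitude 0.35 is
   reduced by 55 %·effect.

Defaults: 50 subjects per class, native grid 128×128 (the cohort the
model family targets is acquired at 512×512 and immediately downsampled;
generating at 128 keeps every analysis grid ≤ 128 reachable while making
a 100-subject cohort cheap to simulate), 20 frames per cycle, noise SD
0.05 on the [0, 1] scale, pose ranges ±6 px translation, ±15° rotation,
scale 0.9–1.1, flip probability 0.25. The first control subject is the
cohort reference (identity pose, carries the five boundary landmarks), so
reference space coincides with canonical space. Landmarks are analytic:
the two septal hinge points are the intersections of the nominal
end-diastolic LV/RV epicardial circles, the free-wall inflection is the
RV circle's leftmost point, and b1–b5 lie on an ellipse (semi-axes
0.34 L × 0.28 L) enclosing the heart. Subjects are rendered by evaluating
the geometry at inverse-posed pixel coordinates, so posed landmarks
correspond exactly and registration residuals are at machine precision in
the noise-free limit.

What the phantom does *not* model: MR physics (coil profiles, k-space,
banding, flow artefacts), anatomical variability beyond a similarity
transform, papillary muscles, through-plane motion, or class overlap in
geometry. Passing the end-to-end tests therefore demonstrates that the
pipeline recovers a known, registered, in-plane class difference under
pose and noise — not that it attains any particular accuracy on clinical
data.

`effect_region_mask` documents where the class effects act (RV disc
+3 px margin, plus the LV septal sector within 3 bump widths); outside
it, class-conditional mean images agree below the noise floor when pose
is disabled, which the test suite asserts.

## Problem sizes used by the test suite and acceptance script

End-to-end studies run at 50 subjects per class, native 128, analysis
grid 64 with the small mask (the configuration the sweep identifies as
strongest); the effect-size grid is {0, 0.25, 0.5, 1.0} at a fixed seed
bank. The null-calibration property (20 seeded label permutations, mean
AUC in [0.45, 0.55]) runs at analysis grid 32 — the property is
grid-independent and the smaller grid keeps the permutation loop cheap.
Unit tests use toy tensors and small cohorts.

## Known limitations

- Single 2-D slice only; no multi-slice or 4-D extension.
- Landmarks are inputs, not detected; garbage landmarks mean garbage
  registration (QA flags, but does not fix, such subjects).
- The per-mode variance threshold (0.97) and S grid are heuristics
  exposed as configuration; the scale/mask sweep is the intended tuning
  surface.
- SVC's hinge loss has no per-sample probability; LR probabilities are
  available but uncalibrated.
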