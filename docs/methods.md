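# Methods

This note records the model assumptions, parameter choices, numerical
details and known limitations of `kfmfit`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Shape model

Training shapes are ordered landmark sets; landmark `l` denotes the same
anatomy in every image. Generalized Procrustes alignment iterates
full-Procrustes fits of each raw shape to the running mean, re-normalizing
the mean to centroid at the origin and unit centroid size
(`sqrt(Σ ‖p_l − c‖²) = 1`), until the mean moves by less than `tol = 1e-7`
(at most 100 iterations). Because centroid/size normalization leaves the
frame's rotation free, the converged frame is rotated so that the mean's
first off-centroid landmark lies at angle zero; landmark indexing is
intrinsic, so the aligned frame is invariant to any similarity transform
applied to the whole training set — a property the tests assert.

PCA keeps the smallest number of modes reaching the requested variance
fraction (default 0.98). Eigenvalues below `1e-12` of the total variance
are discarded rather than capping the mode count explicitly at `2N − 4`;
alignment removes the four similarity degrees of freedom, so the rank
deficiency emerges numerically, while a full-variance basis still
reconstructs training shapes to machine precision. Mode coefficients are
clamped to `±3 √λ` (configurable).

Gray-level profiles are raw intensities sampled bilinearly along the
landmark normal (edge-clamped outside the image); the normal at landmark
`l` is perpendicular to the chord joining landmarks `l−1` and `l+1`
(wrapping on closed contours, one-sided at open ends). The profile
half-length is `m = 6` samples at 1 px spacing — the literature spans
roughly 4–8 for images of this scale, and 6 covers the phantom's smoothed
edge (σ = 1.5 px) with context on both sides. Profiles are not normalized
or differentiated: the mean is taken over raw gray levels as modeled.
This makes profile search sensitive to global intensity shifts between
images, a deliberate simplification; an affine intensity change rescales
profiles exactly (tested), so per-dataset normalization can be applied
upstream if needed.

## Feature backend

The default backend is the SIFT implementation of scikit-image
(difference-of-Gaussian detector, 128-bin gradient histogram descriptor)
with its canonical parameters, exposed through the backend config. The
backend contract is determinism: identical image and config give a
bitwise-identical, (y, x, scale)-sorted feature list. Float images are
min-max normalized to 8 bits before detection. The backend registry
accepts alternative detectors with the same contract; none are shipped.

Descriptor distance is Euclidean. The ratio test accepts the nearest
candidate when its distance is below 0.8 of the second-nearest (Lowe's
convention). A single candidate admits no ratio; it is accepted only
below an absolute cap, set during KFM training to 0.7 of the median
pairwise descriptor distance of the training pool — a scale-free proxy
for "clearly similar".

## Key features model

Training features are mapped to the mean-shape frame by their image's
Procrustes pose. All unordered image pairs are matched once (i < j)
under the three conditions; the geometric gate defaults to 0.05 of the
mean-shape centroid size. Because the mean shape is unit-size, aligned
coordinates are dimensionless; the trained model stores
`reference_scale`, the mean training centroid size in pixels, wherever a
pixel-denominated quantity must be expressed in the aligned frame.

Matched pairs are propagated transitively (connected components of the
match graph). A component holding several features of one image violates
the one-feature-per-position-per-image assumption; the member with the
smallest summed descriptor distance to the members of the other images
is kept and the rest become singleton collections, which any practical
picking ratio then removes. Never-matched features likewise remain
singletons. The picking-ratio comparison uses `≥` so that a ratio of 1.0
is attainable.

Test-image matching follows the mutual-minimum rule: feature `f` matches
collection `k` only if `f` is the test feature nearest to `ā_k` *and*
`f`'s minimum distance to the member descriptors of `C_k` is minimal
over all test features. The second condition can alternatively use the
average descriptor (`second_condition="average"`); member-minimum is the
default. A feature winning several collections keeps the one with the
smallest first-condition distance; the losing collections go unmatched
for that image.

## Displacement prior and MAP pinpointing

For each (collection, landmark) pair, displacements between member
aligned positions and the landmark's aligned position are summarized by
their sample mean and covariance (denominator `n − 1`), with a
regularization floor added to the covariance diagonal: 0.5 px² expressed
in aligned units via `reference_scale`, keeping one- and two-member
collections invertible. Feature presence enters only through which
matches are observed; there is no soft presence weighting.

At test time the learned displacements are mapped into the image frame
by the initialization pose (means rotated and scaled, covariances
conjugated), making the estimator pose-consistent; the product of the
per-feature Gaussians is maximized in closed form as the
precision-weighted mean of the per-feature predictions. All matches vote
for every landmark (no per-landmark gating beyond entry existence). The
closed form is verified against a coarse-to-fine brute-force grid search
(0.05 px resolution) — note the maximizer can fall outside the convex
hull of the individual predictions when precisions are anisotropic.

Pinpointing moves each landmark with MAP evidence to its estimate and
propagates the displacement elastically: landmark `j` receives
`w_ij δ_i` from each targeted landmark `i`, with
`w_ij = min(1, (d_min(i)/d_ij)^γ)`, `γ = 1` by default, and contributions
from multiple targets averaged. The cap at 1 prevents a landmark from
moving farther than the target that drives it; coincident landmarks
inherit the target's displacement verbatim (with a warning). Targeted
landmarks are set exactly to their MAP positions (no blending); both the
exponent and the aggregation are configurable because the elastic rule's
precise form is a genuinely open design point.

## Robust initialization

Correspondences between test-feature positions and KFM mean aligned
positions are filtered by a RANSAC-style consensus search over minimal
two-point similarity hypotheses (500 trials, seeded and deterministic);
inliers lie within the geometric threshold — scaled into the image frame
by the hypothesis scale — of their transformed position, and the largest
consensus set is refit by least squares (Umeyama closed form). This is a
deliberate, declared stand-in for more elaborate mismatch-elimination
schemes; fewer than two matches, or no consensus pair, is an
initialization failure surfaced with its stage name, and an inlier share
below 50% raises a warning flag on the result.

## Iterative profile search

Per iteration each landmark samples an extended profile of
`2(m + k) + 1` values along its current normal (`k = 3` by default, the
middle of the small search windows typical for single-resolution search),
slides the mean profile across the `2k + 1` offsets and moves to the
offset minimizing the summed squared difference; Mahalanobis scoring is
not used because profile covariances are not estimated. The moved shape
is then constrained: its pose to the mean shape is fitted by similarity
Procrustes, the residual is projected into shape space with clamped
coefficients, and the result is mapped back. Landmarks leaving the image
are clamped to the border with a warning. Iteration stops when the
largest landmark movement is below 0.5 px or after 120 iterations
(`converged=False` in the latter case). With `k = 0` the search
degenerates to the constraint projection alone.

## Phantom generator

The generator emulates the data regime the method targets: per-subject
anatomical variation, a clear boundary for profile search, and local
structures that exist in only some subjects.

* Base contour `r(θ) = R (1 + 0.15 cos 2θ + 0.08 sin 3θ)`, `R = 64` px
  in a 288-px image; 8 anchor landmarks at 45° spacing plus 30
  arc-interpolated landmarks (gap counts 4,4,4,4,4,4,3,3) — 38 in total.
* Two radial deformation modes `cos((m+2)θ + φ_m)` with coefficient
  standard deviations 4.0 and 2.5 px: a few-pixel, smooth, low-rank
  deformation comparable to the inter-subject variation a PCA shape
  model is meant to absorb.
* Pose: scale U(0.9, 1.1), rotation U(−0.2, 0.2) rad, translation
  ±14 px — the moderate pose spread of roughly-centered clinical slices.
  Poses that would push the object or a patch outside the frame are
  redrawn (at most 100 times).
* Eight 17-px texture patches (smoothed seeded noise under a Gaussian
  window, amplitude 90 gray levels — far above the 4×noise floor so a
  difference-of-Gaussian detector fires reliably) are stamped at a 24-px
  radial offset from their anchor landmark, each with an independent
  Bernoulli presence: probabilities {0.9, 0.9, 0.9, 0.9, 0.7, 0.7, 0.4,
  0.2} straddle the 0.6 picking ratio, so the KFM should keep structures
  of the first six patches and drop the last two.
* Intensities: background 60, interior 170, boundary smoothed with
  σ = 1.5 px, additive Gaussian noise σ = 5, quantized to uint8.
  Everything derives from one seed; generation is bitwise reproducible.

What the phantom does **not** emulate: MRI intensity bias fields,
partial-volume effects, texture inside the object, correlated
multi-slice anatomy, or structures whose absence correlates with shape.
Passing phantom tests therefore demonstrates the machinery is correct
under the stated regime, not clinical-grade performance.

The spread of keypoints per patch means the KFM typically holds more
than one collection per planted patch, and it legitimately also picks up
repeatable structures of the object itself (e.g. the blob-center
keypoint). Planted-correspondence metrics (repetition ratio, correct
match ratio) are computed over collections attributable to a patch —
attribution by majority vote of member positions within 8 px — since
ground truth exists only for those; a match counts as correct within
8.5 px (half the patch size, i.e. "on the structure"). With two kept
patches present in only ~70% of images, the unconditional mean
repetition ratio is structurally bounded near 0.85 even under perfect
re-detection; the acceptance script therefore reports both the
unconditional ratio and the ratio conditional on patch presence.

## Problem sizes and determinism

The validation suite trains on 60 phantom images and evaluates on 60
held-out images (40 for the iteration-count comparison) — chosen to
mirror a realistic per-group training split while keeping a full
train-plus-evaluate cycle around half a minute on one CPU. All stochastic
steps (phantom sampling, RANSAC) flow from explicit integer seeds; fits
are bitwise reproducible for a fixed model and seed, and the model
archive round-trips losslessly.

## Known limitations

* Profiles are raw gray levels; robustness to intensity non-uniformity
  is the user's responsibility.
* Single-resolution search only; a very poor initialization (beyond the
  `±(m+k)` px capture range of the profile search) will not recover.
* The displacement prior is unimodal Gaussian per (collection,
  landmark); multimodal anatomical relationships are averaged.
* 2-D only; open contours are supported but the defaults assume a closed
  boundary.
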