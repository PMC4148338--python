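# kfmfit

Automatic, landmark-based registration of 2-D grayscale medical images by
compounding two statistical models: a **point distribution model** (PDM) of
the global object shape, and a **key features model** (KFM) of highly
repeatable local invariant features. The package addresses the classic
weakness of active shape models — they must be initialized close to the
target and they fit poorly when anatomy varies between subjects — by
letting robustly matched local keypoints place, and then refine, the
deformable shape automatically.

Intended users: researchers segmenting or co-registering structured 2-D
images (e.g. short-axis cardiac MRI slices) who have a training set of
images with manually labeled landmark contours.

## The model

**Shape.** Training shapes `x_i` (N ordered landmarks) are aligned by
generalized Procrustes analysis under similarity transforms and reduced by
PCA: a legal shape is `x = x̄ + P b` with `|b_j| ≤ 3 √λ_j`. Each landmark
also carries a mean gray-level profile `ḡ_l`, sampled along the boundary
normal, which drives the local search during fitting.

**Key features.** SIFT keypoints from all training images are mapped into
the mean-shape frame using the Procrustes poses. Pairs of features in two
images are matched under three conditions: Lowe's nearest/second-nearest
ratio test (two conditions) plus a geometric gate — the aligned positions
must be closer than a threshold. Matches are propagated transitively
across images into collections; a collection enters the KFM only if its
occurrence ratio `M_k / M` reaches the picking ratio (default 0.6). Each
kept collection stores its mean aligned position and the average
descriptor `ā_k` of its members.

**Displacement prior.** For every collection `k` and landmark `l`, the
displacement `d_{kl}` between the feature and the landmark (mean-shape
frame) is modeled as a bivariate Gaussian. In a test image, matched
features vote for each landmark; the product of Gaussians is maximized in
closed form (a precision-weighted mean), giving a MAP position per
landmark.

**Fitting** runs four stages: (1) match test features to the KFM and
estimate a similarity pose by RANSAC over the correspondences; (2) apply
the pose to the mean shape (rigid initialization); (3) pull each landmark
to its MAP position, propagating each adjustment elastically to nearby
landmarks with inverse-distance weights; (4) iterative profile search
with shape-space constraints until convergence.

## Worked example

Real cardiac data cannot ship with the package, so the built-in phantom
generator produces the same regime: a deformable 38-landmark object with
eight local texture patches that are present in only a fraction of images
(occurrence 0.2–0.9).

```bash
kfmfit synth --output data/train --n-images 60 --seed 11
kfmfit synth --output data/test  --n-images 5  --seed 99
kfmfit train --data data/train --output model.npz
kfmfit fit --model model.npz --image data/test/sample_000.png --output fit0
kfmfit evaluate --predicted fit0_final --reference data/test_refs
```

Training logs `model written to model.npz (16 KFM collections, 2 shape
modes)`: the picking ratio kept 16 repeatable feature collections and PCA
kept 2 deformation modes. A fit report looks like

```json
{
  "status": "ok",
  "n_matched_features": 15,
  "n_pinpointed": 38,
  "iterations": 2,
  "converged": true
}
```

meaning 15 keypoints survived the robust matching (enough to estimate the
pose), all 38 landmarks received MAP evidence, and the profile search
converged in 2 iterations — against roughly 11–13 when started from an
uninformed center position. The same run through the library API:

```python
import kfmfit

cfg = kfmfit.PhantomConfig(n_images=60, seed=11)
samples = kfmfit.generate_dataset(cfg)
model = kfmfit.train_model([s.image for s in samples],
                           [s.shape for s in samples])
test = kfmfit.generate_dataset(kfmfit.PhantomConfig(n_images=1, seed=99))[0]
result = kfmfit.fit_image(test.image, model, seed=1)
print(kfmfit.average_error([result.final_shape], [test.shape]))
```

On held-out phantoms the stages improve monotonically: initialization
error ≈ 2.9 px, after pinpointing ≈ 1.6 px, after the iterative search
≈ 0.4 px (60 images, seeds as in `scripts/acceptance.py`).

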