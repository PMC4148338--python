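"""Model fitting: robust initialization, elastic pinpointing, profile search.

Fitting a trained model to a new image runs four stages. Test-image
features are matched to the KFM and a similarity pose is estimated from
the correspondences by a RANSAC-style consensus search; applying that pose
to the mean shape gives the rigid initialization. Each landmark is then
pulled to its MAP position from the displacement prior, with the
adjustment propagated elastically to neighboring landmarks by inverse
distance weights. Finally, the classic iterative profile search refines
the contour: every landmark slides along its boundary normal to the offset
whose gray-level profile best matches the trained mean profile, and the
moved shape is projected back into the bounded PCA shape space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import SimilarityTransform, estimate_similarity_transform
from .shapes import (
    LandmarkShape,
    ProfileModel,
    ShapeModel,
    boundary_normals,
    project_to_shape_space,
    reconstruct_shape,
    sample_shape_profiles,
)

__all__ = [
    "FitResult",
    "InitializationError",
    "filter_mismatches",
    "initialize_pdm",
    "pinpoint_landmarks",
    "iterative_fit",
    "average_error",
    "evaluation_metrics",
    "matching_metrics",
]


class InitializationError(RuntimeError):
    """Raised when automatic initialization cannot proceed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"initialization failure at stage {stage!r}: {message}")


@dataclass
class FitResult:
    """Shapes and diagnostics of the three fitting stages (test-image frame)."""

    initialized_shape: LandmarkShape
    pinpointed_shape: LandmarkShape
    final_shape: LandmarkShape
    init_transform: SimilarityTransform
    n_matched_features: int
    n_pinpointed: int
    iterations: int
    converged: bool
    low_inlier_warning: bool = False


def _similarity_from_two(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Exact similarity transform through two point pairs (complex ratio)."""
    zs = src[:, 0] + 1j * src[:, 1]
    zd = dst[:, 0] + 1j * dst[:, 1]
    dz = zs[1] - zs[0]
    if dz == 0:
        raise ValueError("coincident source points")
    a = (zd[1] - zd[0]) / dz
    scale = abs(a)
    if scale == 0:
        raise ValueError("coincident target points")
    b = zd[0] - a * zs[0]
    return SimilarityTransform(
        scale=scale,
        rotation=float(np.angle(a)),
        translation=np.array([b.real, b.imag]),
    )


def filter_mismatches(
    matches: Sequence[tuple[np.ndarray, np.ndarray]],
    inlier_threshold: float,
    max_trials: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, SimilarityTransform, bool]:
    """Robust consensus estimation of the initialization pose.

    ``matches`` holds (test-image position, KFM mean aligned position)
    pairs. Minimal two-point similarity hypotheses are scored by inliers:
    a match is an inlier when its transformed KFM position lies within
    ``inlier_threshold`` (mean-shape-frame units, scaled into the test
    frame by the hypothesis scale) of the test position. The largest
    consensus set is refit by least squares.

    Returns ``(inlier_indices, transform, low_inlier_flag)`` with the flag
    raised when fewer than half the matches are inliers.
    """
    if len(matches) < 2:
        raise InitializationError(
            "filter_mismatches", f"need at least 2 matches, got {len(matches)}"
        )
    dst = np.stack([np.asarray(m[0], dtype=float) for m in matches])
    src = np.stack([np.asarray(m[1], dtype=float) for m in matches])
    n = len(matches)

    if n == 2:
        t = _similarity_from_two(src, dst)
        return np.array([0, 1]), t, False

    rng = np.random.default_rng(seed)
    best_inliers = np.zeros(0, dtype=int)
    best_score = (-1, np.inf)
    for _ in range(max_trials):
        i, j = rng.choice(n, size=2, replace=False)
        try:
            t = _similarity_from_two(src[[i, j]], dst[[i, j]])
        except ValueError:
            continue
        resid = np.linalg.norm(t.apply(src) - dst, axis=1)
        thr = inlier_threshold * t.scale
        mask = resid < thr
        score = (int(mask.sum()), float(resid[mask].mean()) if mask.any() else np.inf)
        if score[0] > best_score[0] or (
            score[0] == best_score[0] and score[1] < best_score[1]
        ):
            best_score = score
            best_inliers = np.flatnonzero(mask)
    if len(best_inliers) < 2:
        raise InitializationError(
            "filter_mismatches", "no consensus set of size >= 2 found"
        )
    transform = estimate_similarity_transform(src[best_inliers], dst[best_inliers])
    low = len(best_inliers) < 0.5 * n
    if low:
        warnings.warn(
            f"only {len(best_inliers)}/{n} matches are inliers",
            RuntimeWarning,
            stacklevel=2,
        )
    return best_inliers, transform, low


def initialize_pdm(
    mean_shape: LandmarkShape, transform: SimilarityTransform
) -> LandmarkShape:
    """Rigid initialization: the pose applied to the mean shape.

    The mean-shape geometry is preserved exactly (similarity transform
    only) — deformation happens in the later stages.
    """
    return mean_shape.transformed(transform)


def pinpoint_landmarks(
    initialized: LandmarkShape,
    targets: dict[int, np.ndarray],
    exponent: float = 1.0,
) -> LandmarkShape:
    """Elastic adjustment of the initialized shape toward MAP targets.

    Each targeted landmark i moves by ``delta_i = target_i - init_i``; a
    non-targeted landmark j receives from every target the contribution
    ``w_ij * delta_i`` with ``w_ij = min(1, (d_min(i) / d_ij) ** exponent)``
    where ``d_min(i)`` is the distance from i to its nearest other landmark
    in the initialized shape. Contributions from multiple targets are
    averaged; targeted landmarks are finally set to their targets exactly.
    With no targets the shape is returned unchanged.
    """
    pts = initialized.points.copy()
    if not targets:
        return LandmarkShape(pts)
    n = len(pts)
    tidx = sorted(targets)
    deltas = {i: np.asarray(targets[i], dtype=float) - pts[i] for i in tidx}

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    d_min = dist.min(axis=1)

    targeted = set(tidx)
    coincident_promoted: dict[int, np.ndarray] = {}
    contrib = np.zeros((n, 2))
    counts = np.zeros(n)
    for i in tidx:
        for j in range(n):
            if j in targeted or j in coincident_promoted:
                continue
            d = dist[i, j]
            if d == 0:
                warnings.warn(
                    f"landmarks {i} and {j} coincide; {j} inherits the same "
                    "displacement",
                    RuntimeWarning,
                    stacklevel=2,
                )
                coincident_promoted[j] = pts[j] + deltas[i]
                continue
            w = min(1.0, (d_min[i] / d) ** exponent)
            contrib[j] += w * deltas[i]
            counts[j] += 1

    move = counts > 0
    pts[move] += contrib[move] / counts[move, None]
    for j, p in coincident_promoted.items():
        pts[j] = p
    for i in tidx:
        pts[i] = np.asarray(targets[i], dtype=float)
    return LandmarkShape(pts)


def iterative_fit(
    image: np.ndarray,
    start_shape: LandmarkShape,
    shape_model: ShapeModel,
    profile_model: ProfileModel,
    search_length: int = 3,
    max_iter: int = 120,
    tol: float = 0.5,
) -> tuple[LandmarkShape, int, bool]:
    """Iterative profile search with shape-space constraints.

    Per iteration each landmark samples an extended profile of length
    ``2 (m + k) + 1`` along its boundary normal, slides the trained mean
    profile over the ``2 k + 1`` center offsets and moves to the offset
    minimizing the summed squared gray-level difference; the moved shape
    is then projected into the bounded PCA space (pose fitted by
    similarity Procrustes, coefficients clamped) and mapped back.
    Stops when the largest landmark movement falls below ``tol`` pixels.
    """
    if search_length < 0:
        raise ValueError("search_length must be >= 0")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    m = profile_model.profile_half_length
    k = search_length
    spacing = profile_model.sample_spacing
    mean_prof = profile_model.mean_profiles  # (N, 2m+1)
    mean_pts = shape_model.mean_shape.points

    current = start_shape.points.copy()
    iterations = 0
    converged = False
    warned_border = False
    for _ in range(max_iter):
        shape = LandmarkShape(current)
        ext = sample_shape_profiles(
            img, shape, m + k, spacing, closed=profile_model.closed
        )  # (N, 2(m+k)+1)
        # SSD of the mean profile at each of the 2k+1 offsets
        offs = np.arange(2 * k + 1)
        windows = np.stack(
            [ext[:, o : o + 2 * m + 1] for o in offs], axis=1
        )  # (N, 2k+1, 2m+1)
        ssd = ((windows - mean_prof[:, None, :]) ** 2).sum(axis=2)
        best = ssd.argmin(axis=1) - k  # signed offsets
        normals = boundary_normals(shape, closed=profile_model.closed)
        moved = current + (best * spacing)[:, None] * normals

        out = (
            (moved[:, 0] < 0)
            | (moved[:, 0] > w - 1)
            | (moved[:, 1] < 0)
            | (moved[:, 1] > h - 1)
        )
        if out.any():
            if not warned_border:
                warnings.warn(
                    "landmark left the image during search; clamped to border",
                    RuntimeWarning,
                    stacklevel=2,
                )
                warned_border = True
            moved[:, 0] = np.clip(moved[:, 0], 0, w - 1)
            moved[:, 1] = np.clip(moved[:, 1], 0, h - 1)

        # shape-space constraint: fit pose, clamp coefficients, map back
        pose = estimate_similarity_transform(mean_pts, moved)
        in_model = pose.inverse().apply(moved)
        b = project_to_shape_space(shape_model, LandmarkShape(in_model), clamp=True)
        constrained = pose.apply(reconstruct_shape(shape_model, b).points)

        movement = float(np.linalg.norm(constrained - current, axis=1).max())
        current = constrained
        iterations += 1
        if movement < tol:
            converged = True
            break
    return LandmarkShape(current), iterations, converged


def average_error(
    predicted: Sequence[LandmarkShape], reference: Sequence[LandmarkShape]
) -> float:
    """Mean Euclidean landmark distance over all images and landmarks."""
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference counts differ")
    if not predicted:
        raise ValueError("empty shape lists")
    dists = []
    for p, r in zip(predicted, reference):
        if p.n_landmarks != r.n_landmarks:
            raise ValueError("landmark count mismatch")
        dists.append(np.linalg.norm(p.points - r.points, axis=1))
    return float(np.concatenate(dists).mean())


def evaluation_metrics(
    results: Sequence[FitResult],
    references: Sequence[LandmarkShape],
    init_tolerance: float = 5.0,
    pinpoint_tolerance: float = 3.0,
) -> dict:
    """Per-stage error and the correct-initialization / pinpoint criteria.

    An image counts as correctly initialized when strictly more than half
    of its landmarks lie within ``init_tolerance`` (default 5 px) of the
    reference; a landmark is precisely pinpointed when within
    ``pinpoint_tolerance`` (default 3 px).
    """
    if len(results) != len(references):
        raise ValueError("results and references counts differ")
    correct_init = 0
    pinpoint_counts = []
    for res, ref in zip(results, references):
        n = ref.n_landmarks
        d_init = np.linalg.norm(res.initialized_shape.points - ref.points, axis=1)
        if (d_init < init_tolerance).sum() > n / 2:
            correct_init += 1
        d_pin = np.linalg.norm(res.pinpointed_shape.points - ref.points, axis=1)
        pinpoint_counts.append(int((d_pin < pinpoint_tolerance).sum()))
    return {
        "n_images": len(results),
        "e_avg_initialized": average_error(
            [r.initialized_shape for r in results], references
        ),
        "e_avg_pinpointed": average_error(
            [r.pinpointed_shape for r in results], references
        ),
        "e_avg_final": average_error([r.final_shape for r in results], references),
        "correct_initialization_ratio": correct_init / len(results),
        "pinpoint_counts": pinpoint_counts,
        "mean_pinpoint_count": float(np.mean(pinpoint_counts)),
        "mean_iterations": float(np.mean([r.iterations for r in results])),
    }


def matching_metrics(
    matched_per_image: Sequence[Sequence[tuple[np.ndarray, int]]],
    true_positions_per_image: Sequence[dict[int, np.ndarray]],
    n_collections: int,
    tolerance: float = 6.0,
) -> dict:
    """Repetition ratio per collection and the correct-match ratio.

    ``matched_per_image[i]`` holds (test-frame position, collection index)
    matches in image i; ``true_positions_per_image[i]`` maps a collection
    index to its ground-truth position in that image (absent when the
    underlying structure is not present). A match is correct when its
    position lies within ``tolerance`` pixels of the truth. The repetition
    ratio of a collection is the fraction of test images in which it is
    correctly re-detected; the correct-match ratio is the fraction of all
    matches that are correct.
    """
    n_images = len(matched_per_image)
    if len(true_positions_per_image) != n_images:
        raise ValueError("per-image lists must have equal length")
    correct = np.zeros(n_collections, dtype=int)
    total_matches = 0
    total_correct = 0
    for matches, truth in zip(matched_per_image, true_positions_per_image):
        for pos, k in matches:
            total_matches += 1
            t = truth.get(k)
            if t is not None and np.linalg.norm(np.asarray(pos) - t) < tolerance:
                correct[k] += 1
                total_correct += 1
    return {
        "repetition_ratio": correct / n_images,
        "mean_repetition_ratio": float(correct.mean() / n_images),
        "correct_match_ratio": (
            total_correct / total_matches if total_matches else float("nan")
        ),
        "n_matches": total_matches,
    }
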