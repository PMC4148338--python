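"""Point distribution model: Procrustes alignment, PCA shape space, profiles.

The statistical shape model follows the classic active-shape-model recipe:
training shapes (ordered landmark sets) are brought into a common frame by
generalized Procrustes analysis under similarity transforms, the residual
variation is captured by PCA with bounded mode coefficients, and each
landmark carries a mean gray-level profile sampled along the local boundary
normal, which later drives the image search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import SimilarityTransform, estimate_similarity_transform

__all__ = [
    "LandmarkShape",
    "ShapeModel",
    "ProfileModel",
    "align_shapes",
    "build_shape_model",
    "project_to_shape_space",
    "reconstruct_shape",
    "boundary_normals",
    "sample_profile",
    "sample_shape_profiles",
    "build_profile_model",
]


@dataclass(frozen=True)
class LandmarkShape:
    """Ordered 2-D landmark coordinates of one object instance.

    ``points`` is an (N, 2) float array of (x, y) pixel coordinates
    (0-based, x rightward, y downward). Landmark order is anatomical:
    index l means the same structure in every shape of a dataset.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if pts.shape[0] < 3:
            raise ValueError("a shape needs at least 3 landmarks")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        """Root summed squared distance of landmarks from the centroid."""
        return float(np.sqrt(((self.points - self.centroid) ** 2).sum()))

    def transformed(self, transform: SimilarityTransform) -> "LandmarkShape":
        return LandmarkShape(transform.apply(self.points))


def _normalize(points: np.ndarray) -> np.ndarray:
    """Move centroid to the origin and rescale to unit centroid size."""
    c = points.mean(axis=0)
    centered = points - c
    size = np.sqrt((centered**2).sum())
    if size <= 0:
        raise ValueError("degenerate shape: all landmarks coincide")
    return centered / size


def align_shapes(
    shapes: list[LandmarkShape],
    tol: float = 1e-7,
    max_iter: int = 100,
) -> tuple[list[LandmarkShape], list[SimilarityTransform], LandmarkShape]:
    """Generalized Procrustes alignment of a set of shapes.

    Iteratively aligns every shape to the current mean with a full
    (similarity) Procrustes fit, then re-estimates and re-normalizes the
    mean, until the mean moves by less than ``tol``. The common frame is
    fixed by the declared normalization: centroid at the origin, unit
    centroid size.

    Returns ``(aligned, transforms, mean)`` where ``transforms[i]`` maps
    ``shapes[i]`` onto ``aligned[i]`` and ``mean`` is the per-landmark
    average of the aligned shapes (normalized).
    """
    if len(shapes) < 2:
        raise ValueError("alignment needs at least 2 shapes")
    n = shapes[0].n_landmarks
    if any(s.n_landmarks != n for s in shapes):
        raise ValueError("all shapes must have the same landmark count")

    raw = [s.points for s in shapes]
    aligned = [_normalize(p) for p in raw]
    mean = _normalize(np.mean(aligned, axis=0))

    converged = False
    for _ in range(max_iter):
        aligned = [
            estimate_similarity_transform(p, mean).apply(p) for p in raw
        ]
        new_mean = _normalize(np.mean(aligned, axis=0))
        delta = np.abs(new_mean - mean).max()
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Procrustes alignment did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    # canonical orientation: rotate the common frame so that the mean's
    # first off-centroid landmark sits at angle zero. Landmark indexing is
    # intrinsic, so the aligned frame is invariant to any similarity
    # transform applied to the whole training set.
    norms = np.linalg.norm(mean, axis=1)
    ref_lm = int(np.argmax(norms > 1e-9 * norms.max()))
    ang = np.arctan2(mean[ref_lm, 1], mean[ref_lm, 0])
    c, s = np.cos(-ang), np.sin(-ang)
    rot = np.array([[c, -s], [s, c]])
    mean = mean @ rot.T
    aligned = [a @ rot.T for a in aligned]

    transforms = [
        estimate_similarity_transform(p, a) for p, a in zip(raw, aligned)
    ]
    return (
        [LandmarkShape(a) for a in aligned],
        transforms,
        LandmarkShape(mean),
    )


@dataclass(frozen=True)
class ShapeModel:
    """PCA shape space over aligned landmark configurations.

    ``modes`` holds q orthonormal eigenvectors (columns) over the 2N
    flattened coordinates; ``eigenvalues`` are the matching variances in
    descending order. New shapes are ``mean + modes @ b`` with each
    coefficient bounded by ``bound_multiplier * sqrt(eigenvalue)``.
    """

    mean_shape: LandmarkShape
    modes: np.ndarray  # (2N, q)
    eigenvalues: np.ndarray  # (q,)
    total_variance: float
    bound_multiplier: float = 3.0

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.n_landmarks


def build_shape_model(
    aligned: list[LandmarkShape],
    variance_fraction: float = 0.98,
    bound_multiplier: float = 3.0,
) -> ShapeModel:
    """PCA over aligned shapes keeping the smallest mode count whose
    eigenvalues reach ``variance_fraction`` of the total variance."""
    if len(aligned) < 2:
        raise ValueError("need at least 2 shapes to build a shape model")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")

    x = np.stack([s.points.ravel() for s in aligned])  # (n, 2N)
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centered data; eigenvalues of the sample covariance (n-1)
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = svals**2 / (len(aligned) - 1)
    total = float(eigvals.sum())

    if total <= 0:
        modes = np.zeros((x.shape[1], 0))
        eigvals_kept = np.zeros(0)
    else:
        # drop numerically-zero directions (alignment removes 4 dof)
        keep = eigvals > 1e-12 * total
        eigvals, vt = eigvals[keep], vt[keep]
        cum = np.cumsum(eigvals) / total
        q = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        q = min(q, len(eigvals))
        modes = vt[:q].T
        eigvals_kept = eigvals[:q]

    return ShapeModel(
        mean_shape=LandmarkShape(mean.reshape(-1, 2)),
        modes=modes,
        eigenvalues=eigvals_kept,
        total_variance=total,
        bound_multiplier=bound_multiplier,
    )


def project_to_shape_space(
    model: ShapeModel, shape: LandmarkShape, clamp: bool = True
) -> np.ndarray:
    """Mode coefficients ``b = P^T (x - mean)`` of an aligned-frame shape,
    clamped to ``+/- bound_multiplier * sqrt(lambda_i)``."""
    if shape.n_landmarks != model.n_landmarks:
        raise ValueError(
            f"landmark count mismatch: {shape.n_landmarks} vs "
            f"{model.n_landmarks}"
        )
    b = model.modes.T @ (shape.points.ravel() - model.mean_shape.points.ravel())
    if clamp and model.n_modes:
        lim = model.bound_multiplier * np.sqrt(model.eigenvalues)
        b = np.clip(b, -lim, lim)
    return b


def reconstruct_shape(model: ShapeModel, shape_params: np.ndarray) -> LandmarkShape:
    """Shape ``mean + P b`` for a coefficient vector of length q."""
    b = np.asarray(shape_params, dtype=float).ravel()
    if b.shape[0] != model.n_modes:
        raise ValueError(
            f"expected {model.n_modes} parameters, got {b.shape[0]}"
        )
    flat = model.mean_shape.points.ravel() + model.modes @ b
    return LandmarkShape(flat.reshape(-1, 2))


def boundary_normals(shape: LandmarkShape, closed: bool = True) -> np.ndarray:
    """Unit normals per landmark, perpendicular to the chord joining the
    two neighboring landmarks (one-sided at open-contour ends)."""
    pts = shape.points
    n = len(pts)
    if closed:
        nxt = np.roll(pts, -1, axis=0)
        prv = np.roll(pts, 1, axis=0)
        chord = nxt - prv
    else:
        chord = np.empty_like(pts)
        chord[1:-1] = pts[2:] - pts[:-2]
        chord[0] = pts[1] - pts[0]
        chord[-1] = pts[-1] - pts[-2]
    normals = np.c_[chord[:, 1], -chord[:, 0]]
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-length chord: coincident neighbor landmarks")
    return normals / norms


def sample_profile(
    image: np.ndarray,
    point: np.ndarray,
    normal_direction: np.ndarray,
    half_length: int = 6,
    spacing: float = 1.0,
) -> np.ndarray:
    """Bilinear gray-level samples along the normal through ``point``.

    Returns ``2 * half_length + 1`` values centered at the point; sample
    sites outside the image are edge-clamped.
    """
    nrm = np.asarray(normal_direction, dtype=float)
    nn = np.linalg.norm(nrm)
    if nn == 0:
        raise ValueError("normal direction must be non-zero")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nrm = nrm / nn
    offsets = np.arange(-half_length, half_length + 1) * spacing
    pts = np.asarray(point, dtype=float) + offsets[:, None] * nrm
    return map_coordinates(
        np.asarray(image, dtype=float),
        [pts[:, 1], pts[:, 0]],  # (row, col) = (y, x)
        order=1,
        mode="nearest",
    )


def sample_shape_profiles(
    image: np.ndarray,
    shape: LandmarkShape,
    half_length: int,
    spacing: float = 1.0,
    closed: bool = True,
) -> np.ndarray:
    """Profiles for all landmarks of a shape in one interpolation call.

    Returns an (N, 2*half_length+1) array.
    """
    normals = boundary_normals(shape, closed=closed)
    offsets = np.arange(-half_length, half_length + 1) * spacing
    # (N, L, 2) sample sites
    sites = shape.points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vals = map_coordinates(
        np.asarray(image, dtype=float),
        [sites[..., 1].ravel(), sites[..., 0].ravel()],
        order=1,
        mode="nearest",
    )
    return vals.reshape(shape.n_landmarks, offsets.size)


@dataclass(frozen=True)
class ProfileModel:
    """Per-landmark mean gray-level profiles of length ``2 m + 1``."""

    mean_profiles: np.ndarray  # (N, 2m+1)
    profile_half_length: int
    sample_spacing: float = 1.0
    closed: bool = True

    @property
    def n_landmarks(self) -> int:
        return self.mean_profiles.shape[0]


def build_profile_model(
    images: list[np.ndarray],
    shapes: list[LandmarkShape],
    half_length: int = 6,
    spacing: float = 1.0,
    closed: bool = True,
) -> ProfileModel:
    """Average the per-landmark profiles over all training images.

    A landmark lying outside its image is skipped (with a warning); a
    landmark with no valid sample in any image is an error.
    """
    if len(images) != len(shapes):
        raise ValueError("one shape per image required")
    n = shapes[0].n_landmarks
    length = 2 * half_length + 1
    acc = np.zeros((n, length))
    cnt = np.zeros(n, dtype=int)
    for img, shape in zip(images, shapes):
        h, w = np.asarray(img).shape
        inside = (
            (shape.points[:, 0] >= 0)
            & (shape.points[:, 0] <= w - 1)
            & (shape.points[:, 1] >= 0)
            & (shape.points[:, 1] <= h - 1)
        )
        if not inside.all():
            warnings.warn(
                f"{(~inside).sum()} landmark(s) outside image; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
        profs = sample_shape_profiles(img, shape, half_length, spacing, closed)
        acc[inside] += profs[inside]
        cnt[inside] += 1
    if np.any(cnt == 0):
        raise ValueError(
            f"landmark(s) {np.flatnonzero(cnt == 0).tolist()} have no valid "
            "profile sample in any training image"
        )
    return ProfileModel(
        mean_profiles=acc / cnt[:, None],
        profile_half_length=half_length,
        sample_spacing=spacing,
        closed=closed,
    )
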