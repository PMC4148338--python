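"""Statistical displacement relationship between feature collections and landmarks.

For every (collection k, landmark l) pair the displacement
``feature aligned position - landmark aligned position`` over the
collection's member images is modeled as a bivariate Gaussian. In a test
image, each feature matched to collection k then votes for landmark l with
a Gaussian centered at ``feature position - (pose-transformed) mean
displacement``; the maximum-a-posteriori landmark position is the maximizer
of the product of those Gaussians, which has the closed form of a
precision-weighted mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import SimilarityTransform
from .kfm import KFM
from .shapes import LandmarkShape

__all__ = ["DisplacementModel", "fit_displacement_model", "landmark_map_estimate"]


@dataclass(frozen=True)
class DisplacementModel:
    """Per-(collection, landmark) bivariate Gaussian displacement statistics.

    means: (K, N, 2); covariances: (K, N, 2, 2) symmetric positive-definite
    (a regularization floor is added to the diagonal at fit time);
    sample_counts: (K,) member counts per collection.
    """

    means: np.ndarray
    covariances: np.ndarray
    sample_counts: np.ndarray
    regularization_floor: float

    @property
    def n_collections(self) -> int:
        return self.means.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.means.shape[1]

    def has_entry(self, k: int, l: int) -> bool:
        return 0 <= k < self.n_collections and self.sample_counts[k] >= 1


def fit_displacement_model(
    kfm: KFM,
    aligned_shapes: Sequence[LandmarkShape],
    regularization_floor: float = 0.5,
) -> DisplacementModel:
    """Estimate displacement statistics in the mean-shape frame.

    ``aligned_shapes`` are the Procrustes-aligned training shapes indexed
    by image id. ``regularization_floor`` (squared frame units; 0.5 px^2
    when the frame is in pixels) is added to the covariance diagonal so
    that small collections stay invertible.
    """
    if regularization_floor <= 0:
        raise ValueError("regularization_floor must be positive")
    n_landmarks = aligned_shapes[0].n_landmarks
    k_count = kfm.n_collections
    means = np.zeros((k_count, n_landmarks, 2))
    covs = np.zeros((k_count, n_landmarks, 2, 2))
    counts = np.zeros(k_count, dtype=int)
    eye = np.eye(2) * regularization_floor

    for k, coll in enumerate(kfm.collections):
        positions = np.stack([m.aligned_position for m in coll.members])  # (M, 2)
        lms = np.stack(
            [aligned_shapes[m.image_id].points for m in coll.members]
        )  # (M, N, 2)
        disp = positions[:, None, :] - lms  # (M, N, 2)
        counts[k] = len(coll.members)
        means[k] = disp.mean(axis=0)
        if counts[k] == 1:
            warnings.warn(
                f"collection {k} has a single member; covariance set to the "
                "regularization floor",
                RuntimeWarning,
                stacklevel=2,
            )
            covs[k] = eye
        else:
            centered = disp - means[k]
            covs[k] = (
                np.einsum("mli,mlj->lij", centered, centered) / (counts[k] - 1)
                + eye
            )
    return DisplacementModel(
        means=means,
        covariances=covs,
        sample_counts=counts,
        regularization_floor=regularization_floor,
    )


def landmark_map_estimate(
    matches: Sequence[tuple[np.ndarray, int]],
    model: DisplacementModel,
    landmark: int,
    transform: Optional[SimilarityTransform] = None,
) -> Optional[np.ndarray]:
    """MAP position of one landmark from matched features.

    ``matches`` holds (test-frame feature position, collection index)
    pairs; ``transform`` maps the mean-shape frame to the test frame and is
    applied to the learned displacements (rotating/scaling means,
    conjugating covariances). Maximizing the product of the per-feature
    Gaussians gives the precision-weighted mean of the per-feature
    predictions ``position - transformed mean displacement``.

    Returns ``None`` when no match has a usable (k, l) entry — the caller
    keeps the initialized position.
    """
    transform = transform or SimilarityTransform()
    w_sum = np.zeros((2, 2))
    wp_sum = np.zeros(2)
    n_used = 0
    for pos, k in matches:
        if not model.has_entry(k, landmark):
            continue
        pred = np.asarray(pos, dtype=float) - transform.apply_vector(
            model.means[k, landmark]
        )
        cov = transform.transform_covariance(model.covariances[k, landmark])
        w = np.linalg.inv(cov)
        w_sum += w
        wp_sum += w @ pred
        n_used += 1
    if n_used == 0:
        return None
    return np.linalg.solve(w_sum, wp_sum)
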