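"""2-D similarity transforms and their least-squares estimation.

A similarity transform is the rigid pose used everywhere in this package:
``x' = s R(theta) x + t`` with isotropic scale ``s > 0``, rotation ``theta``
(radians, counter-clockwise in the (x, y) convention with y pointing down)
and translation ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimilarityTransform", "estimate_similarity_transform"]


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class SimilarityTransform:
    """Scale + rotation + translation acting on (x, y) points."""

    scale: float = 1.0
    rotation: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        t = np.asarray(self.translation, dtype=float).reshape(2)
        object.__setattr__(self, "translation", t)

    @property
    def linear(self) -> np.ndarray:
        """The 2x2 matrix ``s R``."""
        return self.scale * _rotation_matrix(self.rotation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array (or a single point) of coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Transform displacement vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.linear.T

    def transform_covariance(self, cov: np.ndarray) -> np.ndarray:
        """Conjugate a 2x2 covariance: ``(sR) C (sR)^T``."""
        a = self.linear
        return a @ np.asarray(cov, dtype=float) @ a.T

    def inverse(self) -> "SimilarityTransform":
        inv_lin = _rotation_matrix(-self.rotation) / self.scale
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation=-self.rotation,
            translation=-(inv_lin @ self.translation),
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return SimilarityTransform(
            scale=self.scale * other.scale,
            rotation=self.rotation + other.rotation,
            translation=self.apply(other.translation),
        )


def estimate_similarity_transform(
    source: np.ndarray, target: np.ndarray
) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``source`` onto ``target``.

    Closed-form (Umeyama / full Procrustes) solution minimising
    ``sum_i || s R source_i + t - target_i ||^2``.

    Parameters
    ----------
    source, target
        Matched (N, 2) point arrays, N >= 2, with non-coincident sources.
    """
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source/target must be matching (N, 2) arrays")
    if src.shape[0] < 2:
        raise ValueError("need at least 2 point pairs")

    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    src_c = src - mu_s
    dst_c = dst - mu_d
    var_s = (src_c**2).sum() / len(src)
    if var_s <= 0:
        raise ValueError("degenerate input: all source points coincide")

    # cross-covariance; rotation from its SVD with det correction
    cov = dst_c.T @ src_c / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    dsign = np.array([1.0, d])
    rot = u @ np.diag(dsign) @ vt
    scale = float((s * dsign).sum() / var_s)
    if scale <= 0:
        raise ValueError("degenerate configuration: non-positive scale")
    theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    t = mu_d - scale * (rot @ mu_s)
    return SimilarityTransform(scale=scale, rotation=theta, translation=t)
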