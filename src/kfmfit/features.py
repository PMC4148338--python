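"""Local invariant feature extraction behind a pluggable backend registry.

The default backend is a SIFT detector/descriptor (difference-of-Gaussian
extrema with 128-d gradient-histogram descriptors). Backends are pure
functions registered by name; a backend must be deterministic — the same
image and configuration always yield the identical feature list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "LocalFeature",
    "FeatureBackendConfig",
    "register_backend",
    "extract_features",
    "descriptor_distance",
    "ratio_test_match",
]


@dataclass(frozen=True)
class LocalFeature:
    """A detected keypoint with appearance descriptor.

    position: (x, y) pixel coordinate; scale: detection scale (sigma);
    orientation: radians; descriptor: fixed-length float vector;
    image_id: index of the source image within its dataset.
    """

    position: np.ndarray
    scale: float
    orientation: float
    descriptor: np.ndarray
    image_id: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(2)
        )
        object.__setattr__(
            self, "descriptor", np.asarray(self.descriptor, dtype=float).ravel()
        )
        if not self.scale > 0:
            raise ValueError("feature scale must be positive")


@dataclass(frozen=True)
class FeatureBackendConfig:
    backend_name: str = "sift"
    params: dict = field(default_factory=dict)
    descriptor_length: int = 128


_BACKENDS: dict[str, Callable] = {}


def register_backend(name: str):
    """Decorator registering ``fn(image, config) -> list[LocalFeature]``."""

    def wrap(fn):
        _BACKENDS[name] = fn
        return fn

    return wrap


def _to_uint8(image: np.ndarray) -> np.ndarray:
    """Accept 8-bit or float grayscale; normalize floats to the 0-255 range."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.dtype == np.uint8:
        return img
    img = img.astype(float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255).astype(np.uint8)


@register_backend("sift")
def _sift_backend(image: np.ndarray, config: FeatureBackendConfig):
    from skimage.feature import SIFT

    det = SIFT(**config.params)
    try:
        det.detect_and_extract(_to_uint8(image))
    except RuntimeError:
        return []  # no stable extrema (e.g. a blank image)
    kp = det.keypoints.astype(float)  # (row, col)
    order = np.lexsort((det.sigmas, kp[:, 1], kp[:, 0]))  # by (y, x, scale)
    return [
        LocalFeature(
            position=(kp[i, 1], kp[i, 0]),
            scale=float(det.sigmas[i]),
            orientation=float(det.orientations[i]),
            descriptor=det.descriptors[i],
        )
        for i in order
    ]


def extract_features(
    image: np.ndarray,
    config: Optional[FeatureBackendConfig] = None,
    image_id: int = -1,
) -> list[LocalFeature]:
    """Run the configured backend on a grayscale image.

    Deterministic for a fixed (image, config); features come back sorted
    by (y, x, scale). An empty list is a legal result.
    """
    config = config or FeatureBackendConfig()
    if config.backend_name not in _BACKENDS:
        raise ValueError(
            f"unknown feature backend {config.backend_name!r}; "
            f"registered: {sorted(_BACKENDS)}"
        )
    img = np.asarray(image)
    if min(img.shape) < 16:
        raise ValueError("image sides must be at least 16 px")
    feats = _BACKENDS[config.backend_name](img, config)
    if image_id != -1:
        feats = [
            LocalFeature(f.position, f.scale, f.orientation, f.descriptor, image_id)
            for f in feats
        ]
    return feats


def descriptor_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-length descriptors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"descriptor length mismatch: {a.size} vs {b.size}")
    return float(np.linalg.norm(a - b))


def _tie_key(f: LocalFeature):
    return (f.image_id, f.position[1], f.position[0])


def ratio_test_match(
    query: LocalFeature,
    candidates: list[LocalFeature],
    ratio_threshold: float = 0.8,
    absolute_cap: Optional[float] = None,
) -> Optional[LocalFeature]:
    """Lowe's nearest/second-nearest ratio test.

    The nearest candidate is accepted iff its descriptor distance is below
    ``ratio_threshold`` times the second-nearest distance. With a single
    candidate no ratio exists: it is accepted iff its distance is below
    ``absolute_cap`` (rejected when no cap is given). Ties on distance are
    broken by smallest image_id, then smallest (y, x).
    """
    if not 0 < ratio_threshold < 1:
        raise ValueError("ratio_threshold must be in (0, 1)")
    if not candidates:
        return None
    dists = np.array(
        [descriptor_distance(query.descriptor, c.descriptor) for c in candidates]
    )
    order = sorted(range(len(candidates)), key=lambda i: (dists[i], _tie_key(candidates[i])))
    best = candidates[order[0]]
    if len(candidates) == 1:
        if absolute_cap is not None and dists[0] < absolute_cap:
            return best
        return None
    d1, d2 = dists[order[0]], dists[order[1]]
    if d1 < ratio_threshold * d2:
        return best
    return None
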