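"""End-to-end training and fitting of the compound model.

``train_model`` builds the four trained blocks from images + landmark
files: the PCA shape model, the per-landmark profile model, the key
features model, and the feature-to-landmark displacement prior.
``fit_image`` composes the full test-time pipeline and returns a
:class:`kfmfit.fitting.FitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .features import FeatureBackendConfig, extract_features
from .fitting import (
    FitResult,
    InitializationError,
    filter_mismatches,
    initialize_pdm,
    iterative_fit,
    pinpoint_landmarks,
)
from .kfm import KFM, KfmConfig, build_kfm, match_image_to_kfm
from .prior import DisplacementModel, fit_displacement_model, landmark_map_estimate
from .shapes import (
    LandmarkShape,
    ProfileModel,
    ShapeModel,
    align_shapes,
    build_profile_model,
    build_shape_model,
)

__all__ = ["TrainConfig", "FullModel", "train_model", "fit_image"]


@dataclass(frozen=True)
class TrainConfig:
    """All tunables of training and fitting, with field defaults."""

    variance_fraction: float = 0.98
    bound_multiplier: float = 3.0
    profile_half_length: int = 6
    sample_spacing: float = 1.0
    closed_contour: bool = True
    ratio_threshold: float = 0.8
    picking_ratio: float = 0.6
    geometric_threshold: Optional[float] = None  # None -> 0.05 x mean size
    floor_px2: float = 0.5  # displacement covariance floor, px^2
    search_length: int = 3
    max_iterations: int = 120
    convergence_tol: float = 0.5
    elastic_exponent: float = 1.0
    ransac_trials: int = 500
    backend_name: str = "sift"
    backend_params: dict = field(default_factory=dict)

    def feature_config(self) -> FeatureBackendConfig:
        return FeatureBackendConfig(
            backend_name=self.backend_name, params=dict(self.backend_params)
        )


@dataclass
class FullModel:
    """The trained model archive contents."""

    shape_model: ShapeModel
    profile_model: ProfileModel
    kfm: KFM
    displacement_model: DisplacementModel
    reference_scale: float  # mean training centroid size, px per frame unit
    config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def n_landmarks(self) -> int:
        return self.shape_model.n_landmarks


def train_model(
    images: Sequence[np.ndarray],
    shapes: Sequence[LandmarkShape],
    config: Optional[TrainConfig] = None,
) -> FullModel:
    """Train all model blocks from images and their labeled landmarks."""
    config = config or TrainConfig()
    if len(images) != len(shapes):
        raise ValueError("one landmark shape per training image required")
    shapes = list(shapes)
    alignment = align_shapes(shapes)
    aligned, transforms, mean_shape = alignment

    shape_model = build_shape_model(
        aligned,
        variance_fraction=config.variance_fraction,
        bound_multiplier=config.bound_multiplier,
    )
    profile_model = build_profile_model(
        list(images),
        shapes,
        half_length=config.profile_half_length,
        spacing=config.sample_spacing,
        closed=config.closed_contour,
    )
    kfm, _aligned_feats = build_kfm(
        list(images),
        shapes,
        KfmConfig(
            feature_config=config.feature_config(),
            ratio_threshold=config.ratio_threshold,
            geometric_threshold=config.geometric_threshold,
            picking_ratio=config.picking_ratio,
        ),
        alignment=alignment,
    )
    reference_scale = float(np.mean([s.centroid_size for s in shapes]))
    displacement_model = fit_displacement_model(
        kfm,
        aligned,
        regularization_floor=config.floor_px2 / reference_scale**2,
    )
    return FullModel(
        shape_model=shape_model,
        profile_model=profile_model,
        kfm=kfm,
        displacement_model=displacement_model,
        reference_scale=reference_scale,
        config=config,
    )


def fit_image(
    image: np.ndarray, model: FullModel, seed: int = 0
) -> FitResult:
    """Fit a trained model to a new image (initialize, pinpoint, iterate)."""
    config = model.config
    features = extract_features(image, config.feature_config())
    if not features:
        raise InitializationError("extract_features", "no features in test image")
    matches = match_image_to_kfm(features, model.kfm)
    if len(matches) < 2:
        raise InitializationError(
            "match_image_to_kfm", f"only {len(matches)} KFM matches"
        )
    corr = [
        (features[f].position, model.kfm.collections[k].mean_aligned_position)
        for f, k in matches
    ]
    inliers, transform, low = filter_mismatches(
        corr,
        inlier_threshold=model.kfm.geometric_threshold,
        max_trials=config.ransac_trials,
        seed=seed,
    )
    initialized = initialize_pdm(model.shape_model.mean_shape, transform)

    inlier_matches = [
        (features[matches[i][0]].position, matches[i][1]) for i in inliers
    ]
    targets = {}
    for l in range(model.n_landmarks):
        est = landmark_map_estimate(
            inlier_matches, model.displacement_model, l, transform
        )
        if est is not None:
            targets[l] = est
    pinpointed = pinpoint_landmarks(
        initialized, targets, exponent=config.elastic_exponent
    )
    final, iterations, converged = iterative_fit(
        image,
        pinpointed,
        model.shape_model,
        model.profile_model,
        search_length=config.search_length,
        max_iter=config.max_iterations,
        tol=config.convergence_tol,
    )
    return FitResult(
        initialized_shape=initialized,
        pinpointed_shape=pinpointed,
        final_shape=final,
        init_transform=transform,
        n_matched_features=len(inliers),
        n_pinpointed=len(targets),
        iterations=iterations,
        converged=converged,
        low_inlier_warning=low,
    )
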