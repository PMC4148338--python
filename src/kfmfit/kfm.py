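"""Key features model: repeatable local invariant features across a training set.

Training features are mapped into the mean-shape frame with the Procrustes
pose of their image, matched pairwise under three conditions — Lowe's ratio
test (two conditions) plus an aligned-position geometric gate — propagated
into cross-image collections by transitive closure, and filtered by a
picking ratio: only collections occurring in at least that fraction of
training images enter the model. Each kept collection is summarized by its
mean aligned position and the componentwise average of member descriptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import (
    FeatureBackendConfig,
    LocalFeature,
    extract_features,
)
from .geometry import SimilarityTransform
from .shapes import LandmarkShape, align_shapes

__all__ = [
    "AlignedFeature",
    "FeatureCollection",
    "KFM",
    "KfmConfig",
    "align_features_to_mean_shape",
    "match_pairs_with_geometry",
    "propagate_matches",
    "select_by_picking_ratio",
    "compute_average_descriptor",
    "build_kfm",
    "match_image_to_kfm",
]


@dataclass(frozen=True)
class AlignedFeature:
    """A training feature together with its mean-shape-frame position."""

    feature: LocalFeature
    aligned_position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "aligned_position",
            np.asarray(self.aligned_position, dtype=float).reshape(2),
        )

    @property
    def image_id(self) -> int:
        return self.feature.image_id


@dataclass
class FeatureCollection:
    """Aligned features (at most one per image) deemed the same position."""

    members: list[AlignedFeature]
    n_images: int

    def __post_init__(self) -> None:
        ids = [m.image_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("a collection may hold at most one feature per image")

    @property
    def occurrence_ratio(self) -> float:
        return len(self.members) / self.n_images

    @property
    def mean_aligned_position(self) -> np.ndarray:
        return np.mean([m.aligned_position for m in self.members], axis=0)

    @property
    def average_descriptor(self) -> np.ndarray:
        return compute_average_descriptor(self)

    @property
    def member_descriptors(self) -> np.ndarray:
        return np.stack([m.feature.descriptor for m in self.members])


@dataclass
class KFM:
    """The selected highly-repeatable feature collections."""

    collections: list[FeatureCollection]
    picking_ratio: float
    n_training_images: int
    geometric_threshold: float  # mean-shape-frame units

    def __post_init__(self) -> None:
        if not self.collections:
            raise ValueError("a KFM needs at least one collection")
        bad = [
            i
            for i, c in enumerate(self.collections)
            if c.occurrence_ratio < self.picking_ratio
        ]
        if bad:
            raise ValueError(
                f"collections {bad} violate occurrence_ratio >= picking_ratio"
            )

    @property
    def n_collections(self) -> int:
        return len(self.collections)

    @property
    def mean_positions(self) -> np.ndarray:
        return np.stack([c.mean_aligned_position for c in self.collections])

    @property
    def average_descriptors(self) -> np.ndarray:
        return np.stack([c.average_descriptor for c in self.collections])


@dataclass(frozen=True)
class KfmConfig:
    feature_config: FeatureBackendConfig = field(default_factory=FeatureBackendConfig)
    ratio_threshold: float = 0.8
    # None -> 0.05 x mean-shape centroid size
    geometric_threshold: Optional[float] = None
    picking_ratio: float = 0.6


def align_features_to_mean_shape(
    features_per_image: list[list[LocalFeature]],
    transforms: list[SimilarityTransform],
) -> list[list[AlignedFeature]]:
    """Apply each image's Procrustes pose to its features' positions."""
    if len(features_per_image) != len(transforms):
        raise ValueError("need exactly one transform per training image")
    out = []
    for feats, t in zip(features_per_image, transforms):
        out.append(
            [AlignedFeature(f, t.apply(f.position)) for f in feats]
        )
    return out


def _descriptor_matrix(feats: list[AlignedFeature]) -> np.ndarray:
    return np.stack([f.feature.descriptor for f in feats])


def match_pairs_with_geometry(
    feats_i: list[AlignedFeature],
    feats_j: list[AlignedFeature],
    ratio_threshold: float = 0.8,
    geometric_threshold: float = np.inf,
    absolute_cap: Optional[float] = None,
) -> list[tuple[int, int]]:
    """Three-condition matching between the features of two images.

    A pair (a, b) passes iff b wins the ratio test for a among all of
    ``feats_j`` (conditions one and two) and the aligned positions are
    closer than ``geometric_threshold`` (third condition). The returned
    index pairs are one-to-one, resolved greedily by ascending descriptor
    distance.
    """
    if not feats_i or not feats_j:
        return []
    di = _descriptor_matrix(feats_i)
    dj = _descriptor_matrix(feats_j)
    dist = np.sqrt(
        np.maximum(
            (di**2).sum(1)[:, None] + (dj**2).sum(1)[None] - 2 * di @ dj.T, 0
        )
    )
    candidates = []
    for a in range(len(feats_i)):
        order = np.argsort(dist[a], kind="stable")
        b = int(order[0])
        if len(feats_j) == 1:
            if absolute_cap is None or dist[a, 0] >= absolute_cap:
                continue
        else:
            d1, d2 = dist[a, order[0]], dist[a, order[1]]
            if not d1 < ratio_threshold * d2:
                continue
        geo = np.linalg.norm(
            feats_i[a].aligned_position - feats_j[b].aligned_position
        )
        if geo < geometric_threshold:
            candidates.append((dist[a, b], a, b))
    # greedy one-to-one by ascending descriptor distance
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = []
    for _, a, b in candidates:
        if a in used_i or b in used_j:
            continue
        used_i.add(a)
        used_j.add(b)
        pairs.append((a, b))
    return pairs


def _component_to_collections(
    comp: list[AlignedFeature], n_images: int
) -> list[FeatureCollection]:
    """Resolve same-image conflicts inside one connected component.

    When a component holds several features of one image, the member with
    the smallest summed descriptor distance to the members of the *other*
    images is kept; evicted features become singleton collections.
    """
    by_image: dict[int, list[AlignedFeature]] = {}
    for m in comp:
        by_image.setdefault(m.image_id, []).append(m)
    kept: list[AlignedFeature] = []
    evicted: list[AlignedFeature] = []
    for img, group in sorted(by_image.items()):
        if len(group) == 1:
            kept.append(group[0])
            continue
        others = [m for m in comp if m.image_id != img]
        if others:
            odesc = _descriptor_matrix(others)

            def cost(m: AlignedFeature) -> float:
                return float(
                    np.linalg.norm(odesc - m.feature.descriptor, axis=1).sum()
                )
        else:

            def cost(m: AlignedFeature) -> float:
                return 0.0

        group_sorted = sorted(
            group,
            key=lambda m: (cost(m), m.feature.position[1], m.feature.position[0]),
        )
        kept.append(group_sorted[0])
        evicted.extend(group_sorted[1:])
    out = [FeatureCollection(kept, n_images)]
    out.extend(FeatureCollection([m], n_images) for m in evicted)
    return out


def propagate_matches(
    aligned_features: list[list[AlignedFeature]],
    pairs: dict[tuple[int, int], list[tuple[int, int]]],
) -> list[FeatureCollection]:
    """Transitive closure of pairwise matches into feature collections.

    ``pairs[(i, j)]`` lists matched (index-in-i, index-in-j) pairs for the
    unordered image pair i < j. Collections are the connected components of
    the resulting match graph, subject to the at-most-one-feature-per-image
    constraint. Every input feature lands in at most one collection;
    features never matched become no collection at all (they cannot pass
    any positive picking ratio on more than one image anyway and are kept
    as singletons).
    """
    import networkx as nx

    n_images = len(aligned_features)
    g = nx.Graph()
    for i, feats in enumerate(aligned_features):
        for a in range(len(feats)):
            g.add_node((i, a))
    for (i, j), plist in pairs.items():
        if i == j:
            raise ValueError("pairs must connect distinct images")
        for a, b in plist:
            g.add_edge((i, a), (j, b))

    collections: list[FeatureCollection] = []
    for comp_nodes in sorted(nx.connected_components(g), key=min):
        comp = [aligned_features[i][a] for i, a in sorted(comp_nodes)]
        collections.extend(_component_to_collections(comp, n_images))
    return collections


def select_by_picking_ratio(
    collections: list[FeatureCollection],
    picking_ratio: float,
    n_images: Optional[int] = None,
) -> list[FeatureCollection]:
    """Keep collections with occurrence ratio >= the picking ratio."""
    if not 0 < picking_ratio <= 1:
        raise ValueError("picking_ratio must be in (0, 1]")
    kept = [c for c in collections if c.occurrence_ratio >= picking_ratio]
    if not kept:
        raise ValueError(
            f"no collection reaches picking_ratio={picking_ratio}; "
            "initialization would fail — lower the ratio"
        )
    return kept


def compute_average_descriptor(collection: FeatureCollection) -> np.ndarray:
    """Componentwise mean of the member descriptors."""
    if not collection.members:
        raise ValueError("cannot average an empty collection")
    return collection.member_descriptors.mean(axis=0)


def _median_pairwise_descriptor_distance(
    aligned_features: list[list[AlignedFeature]], rng_cap: int = 2000
) -> float:
    pool = [m.feature.descriptor for feats in aligned_features for m in feats]
    if len(pool) < 2:
        return np.inf
    pool = np.stack(pool[:rng_cap])
    d2 = (
        (pool**2).sum(1)[:, None] + (pool**2).sum(1)[None] - 2 * pool @ pool.T
    )
    iu = np.triu_indices(len(pool), k=1)
    return float(np.median(np.sqrt(np.maximum(d2[iu], 0))))


def build_kfm(
    images: list[np.ndarray],
    shapes: list[LandmarkShape],
    config: Optional[KfmConfig] = None,
    alignment: Optional[tuple] = None,
    features_per_image: Optional[list[list[LocalFeature]]] = None,
) -> tuple[KFM, list[list[AlignedFeature]]]:
    """Full KFM training pipeline.

    extract -> align to mean-shape frame -> three-condition matching over
    all unordered image pairs -> matching propagation -> picking-ratio
    filter. ``alignment`` may carry a precomputed
    ``(aligned_shapes, transforms, mean_shape)`` from
    :func:`kfmfit.shapes.align_shapes` to avoid re-alignment.

    Returns the KFM and the per-image aligned features (useful for fitting
    the displacement model on the same training pass).
    """
    config = config or KfmConfig()
    if len(images) != len(shapes):
        raise ValueError("one landmark shape per training image required")
    if alignment is None:
        alignment = align_shapes(shapes)
    _, transforms, mean_shape = alignment

    if features_per_image is None:
        features_per_image = [
            extract_features(img, config.feature_config, image_id=i)
            for i, img in enumerate(images)
        ]
    else:
        features_per_image = [
            [
                LocalFeature(f.position, f.scale, f.orientation, f.descriptor, i)
                for f in feats
            ]
            for i, feats in enumerate(features_per_image)
        ]
    aligned = align_features_to_mean_shape(features_per_image, transforms)

    geo = config.geometric_threshold
    if geo is None:
        geo = 0.05 * mean_shape.centroid_size
    cap = 0.7 * _median_pairwise_descriptor_distance(aligned)

    n = len(images)
    pairs = {}
    for i in range(n):
        for j in range(i + 1, n):
            p = match_pairs_with_geometry(
                aligned[i],
                aligned[j],
                ratio_threshold=config.ratio_threshold,
                geometric_threshold=geo,
                absolute_cap=cap,
            )
            if p:
                pairs[(i, j)] = p

    collections = propagate_matches(aligned, pairs)
    kept = select_by_picking_ratio(collections, config.picking_ratio, n)
    kfm = KFM(
        collections=kept,
        picking_ratio=config.picking_ratio,
        n_training_images=n,
        geometric_threshold=geo,
    )
    return kfm, aligned


def match_image_to_kfm(
    test_features: list[LocalFeature],
    kfm: KFM,
    second_condition: str = "members",
) -> list[tuple[int, int]]:
    """Match a test image's features to KFM collections.

    Feature f matches collection k iff (i) f is the test feature closest to
    the collection's average descriptor, and (ii) f's minimum distance to
    the collection's member descriptors (or to the average descriptor when
    ``second_condition='average'``) is minimal over all test features. Each
    collection yields at most one match; a feature winning several
    collections is assigned to the one with the smallest condition-(i)
    distance.

    Returns (test feature index, collection index) pairs.
    """
    if not test_features:
        return []
    if second_condition not in ("members", "average"):
        raise ValueError("second_condition must be 'members' or 'average'")
    desc = np.stack([f.descriptor for f in test_features])  # (F, D)
    avg = kfm.average_descriptors  # (K, D)
    d_avg = np.sqrt(
        np.maximum(
            (desc**2).sum(1)[:, None] + (avg**2).sum(1)[None] - 2 * desc @ avg.T,
            0,
        )
    )  # (F, K)

    proposals: dict[int, tuple[float, int]] = {}  # feature -> (dist, collection)
    for k, coll in enumerate(kfm.collections):
        f_star = int(np.argmin(d_avg[:, k]))
        if second_condition == "members":
            mem = coll.member_descriptors
            d_mem = np.sqrt(
                np.maximum(
                    (desc**2).sum(1)[:, None]
                    + (mem**2).sum(1)[None]
                    - 2 * desc @ mem.T,
                    0,
                )
            ).min(axis=1)
        else:
            d_mem = d_avg[:, k]
        if int(np.argmin(d_mem)) != f_star:
            continue
        d = float(d_avg[f_star, k])
        if f_star not in proposals or d < proposals[f_star][0]:
            proposals[f_star] = (d, k)
    return sorted((f, k) for f, (_, k) in proposals.items())
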