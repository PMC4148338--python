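"""Serialization: landmark point files and the single-file model archive.

Landmark point file format (plain text): line 1 holds the integer landmark
count N, followed by N lines of "x y" (floats, space-separated, printed at
6 decimals). CRLF line endings and blank trailing lines are tolerated.

The model archive is a single ``.npz`` container of named arrays plus a
JSON manifest (key ``manifest``) recording the format version and the
training configuration. Ragged per-collection KFM data is stored as
concatenated member arrays with an offsets index.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np

from .features import LocalFeature
from .kfm import KFM, AlignedFeature, FeatureCollection
from .pipeline import FullModel, TrainConfig
from .prior import DisplacementModel
from .shapes import LandmarkShape, ProfileModel, ShapeModel

__all__ = [
    "ArchiveError",
    "FORMAT_VERSION",
    "save_model",
    "load_model",
    "read_landmarks",
    "write_landmarks",
]

FORMAT_VERSION = "1.0"


class ArchiveError(RuntimeError):
    """A model archive is missing, corrupt, or of an unknown version."""


def save_model(model: FullModel, path: Union[str, Path]) -> None:
    """Write a trained model to a single-file archive (lossless)."""
    kfm = model.kfm
    offsets = np.cumsum([0] + [len(c.members) for c in kfm.collections])
    members = [m for c in kfm.collections for m in c.members]
    manifest = {
        "format_version": FORMAT_VERSION,
        "config": asdict(model.config),
        "n_collections": kfm.n_collections,
    }
    np.savez(
        path,
        manifest=np.array(json.dumps(manifest)),
        shape_mean=model.shape_model.mean_shape.points,
        shape_modes=model.shape_model.modes,
        shape_eigenvalues=model.shape_model.eigenvalues,
        shape_total_variance=np.array(model.shape_model.total_variance),
        shape_bound=np.array(model.shape_model.bound_multiplier),
        profile_means=model.profile_model.mean_profiles,
        profile_half_length=np.array(model.profile_model.profile_half_length),
        profile_spacing=np.array(model.profile_model.sample_spacing),
        profile_closed=np.array(model.profile_model.closed),
        kfm_offsets=offsets,
        kfm_member_descriptors=np.stack([m.feature.descriptor for m in members]),
        kfm_member_aligned_positions=np.stack(
            [m.aligned_position for m in members]
        ),
        kfm_member_image_positions=np.stack([m.feature.position for m in members]),
        kfm_member_scales=np.array([m.feature.scale for m in members]),
        kfm_member_orientations=np.array([m.feature.orientation for m in members]),
        kfm_member_image_ids=np.array([m.image_id for m in members]),
        kfm_picking_ratio=np.array(kfm.picking_ratio),
        kfm_n_training_images=np.array(kfm.n_training_images),
        kfm_geometric_threshold=np.array(kfm.geometric_threshold),
        disp_means=model.displacement_model.means,
        disp_covariances=model.displacement_model.covariances,
        disp_counts=model.displacement_model.sample_counts,
        disp_floor=np.array(model.displacement_model.regularization_floor),
        reference_scale=np.array(model.reference_scale),
    )


def load_model(path: Union[str, Path]) -> FullModel:
    """Read a model archive, validating version and block completeness."""
    path = Path(path)
    try:
        data = np.load(path, allow_pickle=False)
    except (OSError, ValueError, zipfile.BadZipFile) as exc:
        raise ArchiveError(f"cannot read archive {path}: {exc}") from exc

    def block(name: str) -> np.ndarray:
        try:
            return data[name]
        except KeyError as exc:
            raise ArchiveError(f"archive missing block {name!r}") from exc
        except (zipfile.BadZipFile, OSError, ValueError) as exc:
            raise ArchiveError(f"archive block {name!r} is corrupt") from exc

    try:
        manifest = json.loads(str(block("manifest")))
    except json.JSONDecodeError as exc:
        raise ArchiveError("manifest block is corrupt") from exc
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ArchiveError(
            f"unknown archive format_version {version!r}; expected {FORMAT_VERSION}"
        )
    config = TrainConfig(**manifest["config"])

    shape_model = ShapeModel(
        mean_shape=LandmarkShape(block("shape_mean")),
        modes=block("shape_modes"),
        eigenvalues=block("shape_eigenvalues"),
        total_variance=float(block("shape_total_variance")),
        bound_multiplier=float(block("shape_bound")),
    )
    profile_model = ProfileModel(
        mean_profiles=block("profile_means"),
        profile_half_length=int(block("profile_half_length")),
        sample_spacing=float(block("profile_spacing")),
        closed=bool(block("profile_closed")),
    )

    offsets = block("kfm_offsets")
    desc = block("kfm_member_descriptors")
    apos = block("kfm_member_aligned_positions")
    ipos = block("kfm_member_image_positions")
    scales = block("kfm_member_scales")
    orients = block("kfm_member_orientations")
    ids = block("kfm_member_image_ids")
    n_images = int(block("kfm_n_training_images"))
    collections = []
    for k in range(len(offsets) - 1):
        lo, hi = int(offsets[k]), int(offsets[k + 1])
        members = [
            AlignedFeature(
                LocalFeature(
                    position=ipos[i],
                    scale=float(scales[i]),
                    orientation=float(orients[i]),
                    descriptor=desc[i],
                    image_id=int(ids[i]),
                ),
                aligned_position=apos[i],
            )
            for i in range(lo, hi)
        ]
        collections.append(FeatureCollection(members, n_images))
    kfm = KFM(
        collections=collections,
        picking_ratio=float(block("kfm_picking_ratio")),
        n_training_images=n_images,
        geometric_threshold=float(block("kfm_geometric_threshold")),
    )
    displacement_model = DisplacementModel(
        means=block("disp_means"),
        covariances=block("disp_covariances"),
        sample_counts=block("disp_counts"),
        regularization_floor=float(block("disp_floor")),
    )
    return FullModel(
        shape_model=shape_model,
        profile_model=profile_model,
        kfm=kfm,
        displacement_model=displacement_model,
        reference_scale=float(block("reference_scale")),
        config=config,
    )


def read_landmarks(path: Union[str, Path]) -> LandmarkShape:
    """Parse a landmark point file."""
    path = Path(path)
    lines = path.read_text().replace("\r\n", "\n").split("\n")
    # drop blank trailing lines only
    while lines and lines[-1].strip() == "":
        lines.pop()
    if not lines:
        raise ValueError(f"{path}: empty landmark file")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ValueError(f"{path}:1: expected integer landmark count") from exc
    if len(lines) - 1 != n:
        raise ValueError(
            f"{path}: header declares {n} landmarks but file has "
            f"{len(lines) - 1} point lines"
        )
    pts = []
    for i, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"{path}:{i}: expected 'x y', got {line!r}")
        try:
            pts.append((float(tokens[0]), float(tokens[1])))
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: non-numeric token in {line!r}") from exc
    return LandmarkShape(np.array(pts))


def write_landmarks(shape: LandmarkShape, path: Union[str, Path]) -> None:
    """Write a landmark point file (6-decimal precision)."""
    lines = [str(shape.n_landmarks)]
    lines += [f"{x:.6f} {y:.6f}" for x, y in shape.points]
    Path(path).write_text("\n".join(lines) + "\n")
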