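"""Readers and writers: TIFF stacks, detection tables, label volumes, annotations."""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import DEFAULT_VOXEL_SIZE, AnnotationSet, DetectionConfig, ImageVolume

DETECTION_COLUMNS = [
    "id",
    "centroid_z",
    "centroid_y",
    "centroid_x",
    "z_span",
    "n_voxels",
    "total_intensity",
    "max_plane_area_px",
]


def read_volume(
    path: str | os.PathLike,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    channel: str = "",
) -> ImageVolume:
    """Read a multi-page TIFF (or a directory of per-plane TIFFs in lexical
    order) into an :class:`ImageVolume`.

    Plane order is preserved; integer pixel values are promoted to float64
    without rescaling, so a 16-bit voxel of 65535 reads as 65535.0.
    """
    path = Path(path)
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not pages:
            raise ValueError(f"no TIFF planes found in directory {path}")
        planes = [tifffile.imread(p) for p in pages]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent plane shapes in {path}: {sorted(shapes)}")
        data = np.stack(planes, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {data.shape}")
    return ImageVolume(data.astype(np.float64, copy=False), voxel_size, channel)


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page float32 TIFF, one page per z-plane."""
    tifffile.imwrite(Path(path), vol.voxels.astype(np.float32), photometric="minisblack")


def write_detections(
    synapses: Sequence,
    path: str | os.PathLike,
    config: Optional[DetectionConfig] = None,
) -> None:
    """Write one CSV row per synapse; a sidecar ``<path>.config.json`` records
    the full detection configuration including the RNG seed for provenance."""
    rows = [
        {
            "id": s.id,
            "centroid_z": s.centroid[0],
            "centroid_y": s.centroid[1],
            "centroid_x": s.centroid[2],
            "z_span": s.z_span,
            "n_voxels": len(s.voxels),
            "total_intensity": s.total_intensity,
            "max_plane_area_px": s.max_plane_area_px,
        }
        for s in synapses
    ]
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    df.to_csv(path, index=False)
    if config is not None:
        sidecar = Path(str(path) + ".config.json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2))


def write_label_volume(
    synapses: Iterable,
    shape: tuple[int, int, int],
    path: str | os.PathLike,
) -> np.ndarray:
    """Paint each synapse's voxels with its integer id on a zero background.

    Raises if any two voxel sets overlap (labels would collide).
    """
    labels = np.zeros(shape, dtype=np.int32)
    for s in synapses:
        for z, y, x in s.voxels:
            if labels[z, y, x] != 0:
                raise ValueError(
                    f"voxel ({z}, {y}, {x}) claimed by labels {labels[z, y, x]} and {s.id}"
                )
            labels[z, y, x] = s.id
    tifffile.imwrite(Path(path), labels, photometric="minisblack")
    return labels


def read_annotations(path: str | os.PathLike, source: str = "automatic") -> AnnotationSet:
    """Read an annotation set from a label TIFF or a ``label,z,y,x`` CSV.

    Empty labels are dropped.  In CSV form a voxel listed under two labels
    is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        required = {"label", "z", "y", "x"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation CSV needs columns {sorted(required)}")
        seen: dict[tuple[int, int, int], int] = {}
        synapses: dict[int, set] = {}
        for label, z, y, x in df[["label", "z", "y", "x"]].itertuples(index=False):
            vox = (int(z), int(y), int(x))
            label = int(label)
            if vox in seen and seen[vox] != label:
                raise ValueError(f"voxel {vox} assigned to labels {seen[vox]} and {label}")
            seen[vox] = label
            synapses.setdefault(label, set()).add(vox)
        return AnnotationSet({k: frozenset(v) for k, v in synapses.items()}, source=source)

    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[None]
    synapses = {}
    for label in np.unique(labels):
        if label == 0:
            continue
        zs, ys, xs = np.nonzero(labels == label)
        synapses[int(label)] = frozenset(zip(zs.tolist(), ys.tolist(), xs.tolist()))
    return AnnotationSet(synapses, source=source, shape=tuple(labels.shape))


def annotations_from_synapses(synapses: Sequence, shape=None, source="automatic") -> AnnotationSet:
    """Wrap a list of :class:`Synapse3D` as an :class:`AnnotationSet`."""
    return AnnotationSet({s.id: frozenset(s.voxels) for s in synapses}, source=source, shape=shape)


def write_annotations_csv(annotations: AnnotationSet, path: str | os.PathLike) -> None:
    rows = [
        {"label": label, "z": z, "y": y, "x": x}
        for label, vox in sorted(annotations.synapses.items())
        for z, y, x in sorted(vox)
    ]
    pd.DataFrame(rows, columns=["label", "z", "y", "x"]).to_csv(path, index=False)
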