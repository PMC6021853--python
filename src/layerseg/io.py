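"""Readers and writers for the on-disk formats.

Depth images are single-channel 8/16-bit PNGs (or plain numeric text
grids), masks are 0/255 PNGs, label images are indexed PNGs with a JSON
sidecar mapping label values to part names, and part annotations are JSON::

    {"parts": [{"id": 1, "name": "torso", "row": 40, "col": 80}, ...],
     "lines": [[1, 2, 0.667], ...]}

All round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .images import DepthImage
from .pipeline import Part, PartSet

__all__ = [
    "read_depth",
    "write_depth",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_parts",
    "write_parts",
]


def _read_single_channel(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel image, got shape {arr.shape}"
        )
    return arr


def read_depth(path, meters_per_unit: float | None = None) -> DepthImage:
    """Read a depth image from a 8/16-bit single-channel PNG or a text grid."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".csv", ".tsv"):
        values = np.loadtxt(path)
        if values.ndim == 1:
            values = values[None, :]
    else:
        values = _read_single_channel(path)
    return DepthImage(values, meters_per_unit)


def write_depth(depth: DepthImage, path) -> None:
    path = Path(path)
    values = np.asarray(depth.values if isinstance(depth, DepthImage) else depth)
    if path.suffix.lower() in (".txt", ".csv", ".tsv"):
        np.savetxt(path, values, fmt="%.17g")
        return
    if values.min() < 0 or values.max() > np.iinfo(np.uint16).max:
        raise ValueError("depth values do not fit a 16-bit PNG")
    iio.imwrite(path, values.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return _read_single_channel(path) > 0


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_labels(path):
    """Read a label image; returns (labels, names dict from the sidecar)."""
    path = Path(path)
    labels = _read_single_channel(path).astype(np.int64)
    names = {}
    sc = _sidecar(path)
    if sc.exists():
        names = {int(k): v for k, v in json.loads(sc.read_text()).items()}
    return labels, names


def write_labels(labels: np.ndarray, path, names: dict | None = None) -> None:
    """Write a label image as indexed PNG plus a JSON name sidecar."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels do not fit a 16-bit PNG")
    dtype = np.uint8 if labels.max() <= 255 else np.uint16
    iio.imwrite(path, labels.astype(dtype))
    if names is not None:
        _sidecar(path).write_text(
            json.dumps({str(k): v for k, v in sorted(names.items())}, indent=1)
        )


def read_parts(path) -> PartSet:
    data = json.loads(Path(path).read_text())
    if "parts" not in data:
        raise ValueError(f"{path}: missing required 'parts' key")
    parts = [
        Part(int(p["id"]), str(p["name"]), int(p["row"]), int(p["col"]))
        for p in data["parts"]
    ]
    lines = [(int(a), int(b), float(r)) for a, b, r in data.get("lines", [])]
    return PartSet(parts, lines)


def write_parts(parts: PartSet, path) -> None:
    data = {
        "parts": [
            {"id": p.id, "name": p.name, "row": p.row, "col": p.col}
            for p in parts.parts
        ],
        "lines": [[a, b, r] for a, b, r in parts.lines],
    }
    Path(path).write_text(json.dumps(data, indent=1))
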