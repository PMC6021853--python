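"""Raster containers and coercion helpers.

A depth image is a single-channel 2-D raster of depth samples, either in raw
sensor units (e.g. 12-bit Kinect counts) or in metres; the unit is carried as
optional metadata (``meters_per_unit``) so that metric cutoffs can be applied
to raw images.  Foreground masks are plain boolean arrays of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DepthImage", "as_depth", "as_mask"]


@dataclass
class DepthImage:
    """A 2-D depth raster.

    Parameters
    ----------
    values:
        2-D array of depth samples (integer or float).
    meters_per_unit:
        Scale converting raw values to metres, or ``None`` if the unit is
        unknown / the values are already metres.
    """

    values: np.ndarray
    meters_per_unit: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError(
                f"depth image must be a non-empty 2-D array, got shape "
                f"{self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def in_meters(self) -> np.ndarray:
        """Depth values converted to metres (identity if unit unknown)."""
        scale = 1.0 if self.meters_per_unit is None else self.meters_per_unit
        return self.values.astype(float) * scale


def as_depth(depth) -> DepthImage:
    """Coerce an array or :class:`DepthImage` to a :class:`DepthImage`."""
    if isinstance(depth, DepthImage):
        return depth
    return DepthImage(np.asarray(depth))


def as_mask(mask, shape=None) -> np.ndarray:
    """Coerce to a boolean foreground mask and validate it.

    Foreground is any nonzero entry.  Raises if the mask is empty (no
    foreground pixel) or does not match ``shape`` when given.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if shape is not None and m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} does not match image {shape}")
    if not m.any():
        raise ValueError("foreground mask has no foreground pixel")
    return m
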