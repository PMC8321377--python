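"""Binary morphology operators and the three refinement sequences.

Five primitive operators — erosion, dilation, hole filling, area opening and
pixel-wise multiplication (intersection) — are combined into three fixed
sequences:

* Set#1 / Set#2: ``erode -> area_open -> dilate -> multiply`` with the
  pre-refinement detection as the second multiplicand.  The two sets differ
  only in the structuring-element radius: Set#2 serves far/sparse scenes
  whose skin regions are small, so it uses the smaller disk to avoid
  erasing them.
* Set#3: ``erode -> multiply -> fill_holes``, used when the image border is
  saturated with false skin: erosion detaches and removes the thin border
  frame, and hole filling repairs the surviving foreground.

The structuring element is the discrete Euclidean disk
``{(dr, dc): dr^2 + dc^2 <= r^2}``; pixels outside the image are treated as
background for both erosion and dilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import remove_small_objects

__all__ = [
    "MorphConfig",
    "disk_footprint",
    "erode",
    "dilate",
    "fill_holes",
    "area_open",
    "multiply",
    "apply_set",
]


@dataclass(frozen=True)
class MorphConfig:
    """Structuring-element radii for the three sequences and the area floor.

    Radii are in pixels.  ``area_open_min`` is the minimum component area
    kept by the area opening that runs *after* erosion; it is a speck
    scale, sized to remove fragments that erosion left behind while keeping
    the eroded core of any genuine far-scene region (a region of radius
    ~10 px survives Set#2's erosion with well over 50 px).
    """

    disk_radius_set1: int = 3
    disk_radius_set2: int = 2
    disk_radius_set3: int = 3
    area_open_min: int = 50

    def __post_init__(self) -> None:
        if min(self.disk_radius_set1, self.disk_radius_set2, self.disk_radius_set3) < 1:
            raise ValueError("disk radii must be >= 1")
        if self.disk_radius_set1 == self.disk_radius_set2:
            raise ValueError("Set#1 and Set#2 must use different disk radii")
        if self.area_open_min < 1:
            raise ValueError("area_open_min must be >= 1")


def disk_footprint(radius: int) -> np.ndarray:
    """Discrete Euclidean disk: offsets with ``dr^2 + dc^2 <= radius^2``."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return dr * dr + dc * dc <= r * r


def erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion by a disk; out-of-image neighborhood counts as background."""
    return ndi.binary_erosion(
        np.asarray(mask, dtype=bool), structure=disk_footprint(radius), border_value=0
    )


def dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by the same disk (dual of :func:`erode` in the interior)."""
    return ndi.binary_dilation(
        np.asarray(mask, dtype=bool), structure=disk_footprint(radius), border_value=0
    )


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set to skin every background component not connected to the image border."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def area_open(mask: np.ndarray, min_count: int, connectivity: int = 8) -> np.ndarray:
    """Remove connected components with pixel count strictly below ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if min_count == 1:
        return mask.copy()
    # max_size removes components with area <= its value, hence min_count - 1
    return remove_small_objects(
        mask, max_size=min_count - 1, connectivity=2 if connectivity == 8 else 1
    )


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixel-by-pixel product of two binary masks, i.e. their intersection."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a & b


def apply_set(
    mask: np.ndarray,
    set_id: int,
    reference: np.ndarray,
    config: MorphConfig | None = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Apply morphological sequence Set#1, Set#2 or Set#3 to a mask.

    ``reference`` is the unrefined detection mask used by the final (Set#1/2)
    or middle (Set#3) multiplication, clipping any regrowth introduced by
    dilation or hole filling back to originally detected pixels.
    """
    config = config or MorphConfig()
    mask = np.asarray(mask, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if mask.shape != reference.shape:
        raise ValueError("mask and reference must share dimensions")

    if set_id in (1, 2):
        radius = config.disk_radius_set1 if set_id == 1 else config.disk_radius_set2
        out = erode(mask, radius)
        out = area_open(out, config.area_open_min, connectivity)
        out = dilate(out, radius)
        return multiply(out, reference)
    if set_id == 3:
        out = erode(mask, config.disk_radius_set3)
        out = multiply(out, reference)
        return fill_holes(out)
    raise ValueError(f"set_id must be 1, 2 or 3, got {set_id!r}")
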