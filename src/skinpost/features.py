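"""Connected-region labeling and the five scalar features driving class assignment.

The decision tree consumes five per-image scalars computed on the thresholded
skin mask:

* ``skin_ratio`` (SR) — fraction of image pixels labeled skin;
* ``component_count`` (CC) — number of connected skin regions;
* ``border_skin_ratio`` (BSR) — skin fraction of the 1-pixel frame formed by
  the top row and the left/right columns (the bottom row is excluded, since
  bodies commonly exit the frame there);
* ``dominant_ratio`` (SR2) — largest region area over the total skin count;
* ``largest_region_ratio`` (LRR) — largest region area over the image pixel
  count, computed *after* removing lonely (single-pixel) regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "RegionRecord",
    "RegionSet",
    "FeatureVector",
    "label_regions",
    "remove_lonely_pixels",
    "border_skin_ratio",
    "compute_features",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndi.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndi.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class RegionRecord:
    """One connected skin region: positive label, pixel area, inclusive bbox."""

    label: int
    area: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max)


@dataclass
class RegionSet:
    """Connected-component labeling of a mask.

    ``label_grid`` assigns 0 to background and 1..K to regions in
    raster-scan order of each region's first pixel; ``records`` lists one
    entry per region.
    """

    label_grid: np.ndarray
    records: Sequence[RegionRecord]

    @property
    def count(self) -> int:
        return len(self.records)

    @property
    def largest_area(self) -> int:
        return max((r.area for r in self.records), default=0)


def label_regions(mask: np.ndarray, connectivity: int = 8) -> RegionSet:
    """Label maximal connected components of a boolean mask.

    Labels follow raster-scan order of first occurrence, which makes the
    labeling deterministic across runs.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndi.label(mask, structure=_structure(connectivity))
    records: list[RegionRecord] = []
    if n:
        areas = np.bincount(labeled.ravel())
        for lab, sl in enumerate(ndi.find_objects(labeled), start=1):
            records.append(
                RegionRecord(
                    label=lab,
                    area=int(areas[lab]),
                    bbox=(sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1),
                )
            )
    return RegionSet(labeled, records)


def remove_lonely_pixels(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Clear every connected region of area exactly one; larger regions are kept."""
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndi.label(mask, structure=_structure(connectivity))
    if n == 0:
        return mask.copy()
    areas = np.bincount(labeled.ravel())
    keep = areas >= 2
    keep[0] = False
    return keep[labeled]


def border_skin_ratio(mask: np.ndarray) -> float:
    """Skin fraction of the top/left/right 1-pixel border, excluding the bottom row.

    The border set is the top row plus the full left and right columns below
    it (corners counted once), ``width + 2*(height-1)`` pixels in all.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if h < 2 or w < 2:
        raise ValueError("border ratio needs at least a 2x2 image")
    skin = int(mask[0, :].sum()) + int(mask[1:, 0].sum()) + int(mask[1:, w - 1].sum())
    total = w + 2 * (h - 1)
    return skin / total


def compute_features(mask: np.ndarray, connectivity: int = 8) -> "FeatureVector":
    """Compute the five class-assignment features on a thresholded skin mask.

    SR, CC, SR2 and BSR are measured on the mask as given; LRR is measured
    after lonely-pixel removal.  Ratios with an empty denominator are 0.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    n_pixels = h * w
    skin_count = int(mask.sum())

    regions = label_regions(mask, connectivity)
    sr = skin_count / n_pixels
    cc = regions.count
    sr2 = regions.largest_area / skin_count if skin_count else 0.0
    bsr = border_skin_ratio(mask)

    cleaned = remove_lonely_pixels(mask, connectivity)
    cleaned_regions = label_regions(cleaned, connectivity)
    lrr = cleaned_regions.largest_area / n_pixels

    return FeatureVector(sr, cc, bsr, sr2, lrr)


@dataclass(frozen=True)
class FeatureVector:
    """The five scalars consumed by the image-class decision tree."""

    skin_ratio: float
    component_count: int
    border_skin_ratio: float
    dominant_ratio: float
    largest_region_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.skin_ratio <= 1.0:
            raise ValueError("skin_ratio must lie in [0, 1]")
        if self.component_count < 0:
            raise ValueError("component_count must be non-negative")
        if not 0.0 <= self.dominant_ratio <= 1.0:
            raise ValueError("dominant_ratio must lie in [0, 1]")
        if self.largest_region_ratio < 0:
            raise ValueError("largest_region_ratio must be non-negative")
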