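"""Iterative region-homogeneity refinement of a skin probability map.

The refinement repeatedly thresholds the normalized SPM, removes small
regions, and accepts the mask only when every surviving region is
*homogeneous*:

    sigma < sigma_max  AND  (Ne/Nd <= edge_bbox_max  OR  Ne/Ns <= edge_skin_max)

where ``sigma`` is the population standard deviation of the region's SPM
values (on the [0, 255] scale), ``Ne`` the number of region pixels flagged
as edges by the Sobel operator, ``Ns`` the region's pixel count, and ``Nd``
the larger side of its bounding box.  ``Ne/Nd`` is a perimeter-to-diameter
ratio (roughly pi for a disk, 4 for a square — the 3.5 default admits
compact round regions) and ``Ne/Ns`` a perimeter-to-area ratio that large
regions satisfy regardless of shape.  If any region fails, the threshold is
raised by 10% and the loop repeats; because the threshold grows
geometrically the mask is eventually empty and acceptance becomes vacuous,
so the procedure always terminates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel

from .features import _structure

__all__ = [
    "HomogeneityParams",
    "RegionHomogeneity",
    "edge_magnitude",
    "region_stats",
    "is_homogeneous",
    "iterate_refinement",
    "homogeneity_refine",
]


@dataclass(frozen=True)
class HomogeneityParams:
    """Tunable parameters of the homogeneity refinement.

    ``t0`` is the initial threshold on the normalized SPM (skin iff value
    strictly above it) and ``growth`` the multiplicative step applied when a
    region fails.  ``min_area`` (pixels) removes small regions before the
    check.  ``sigma_max`` is on the 8-bit intensity scale; the two edge
    ratios are dimensionless.  ``sobel_threshold`` is the gradient-magnitude
    cutoff, on the [0, 255] scale, above which a region pixel counts as an
    edge pixel; 128 flags pixels whose 3x3 window substantially crosses a
    strong mask boundary while ignoring interior noise.  ``grouped_or``
    fixes operator precedence as sigma AND (ratio OR ratio); the alternative
    ((sigma AND ratio) OR ratio) is available for sensitivity analysis.
    """

    t0: float = 0.2
    growth: float = 1.10
    min_area: int = 300
    sigma_max: float = 45.0
    edge_bbox_max: float = 3.5
    edge_skin_max: float = 0.02
    t_cap: float = 1.0
    sobel_threshold: float = 128.0
    grouped_or: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.t0 < 1.0:
            raise ValueError("t0 must lie in (0, 1)")
        if self.growth <= 1.0:
            raise ValueError("growth must exceed 1")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


@dataclass(frozen=True)
class RegionHomogeneity:
    """Per-region statistics entering the homogeneity criterion."""

    sigma: float
    n_edge: int
    n_skin: int
    bbox_extent: int

    def __post_init__(self) -> None:
        if self.n_skin < 1 or self.bbox_extent < 1:
            raise ValueError("region must be non-empty")


def edge_magnitude(spm: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude of the normalized SPM, rescaled to [0, 255]."""
    return sobel(np.asarray(spm, dtype=np.float64) / 255.0) * 255.0


def region_stats(
    spm: np.ndarray,
    region: np.ndarray,
    bbox: tuple[int, int, int, int] | None = None,
    sobel_threshold: float = 128.0,
    gradient: np.ndarray | None = None,
) -> RegionHomogeneity:
    """Measure one region of an SPM.

    ``region`` is a boolean mask of the region's pixels; ``bbox`` is its
    inclusive (row_min, col_min, row_max, col_max) and is derived from the
    region when omitted.  ``gradient`` allows reusing a precomputed
    :func:`edge_magnitude` image.
    """
    spm = np.asarray(spm)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    if gradient is None:
        gradient = edge_magnitude(spm)
    if bbox is None:
        rows, cols = np.nonzero(region)
        bbox = (rows.min(), cols.min(), rows.max(), cols.max())

    values = spm[region].astype(np.float64)
    sigma = float(values.std())  # population standard deviation
    n_edge = int((gradient[region] > sobel_threshold).sum())
    n_skin = int(region.sum())
    extent = max(bbox[2] - bbox[0] + 1, bbox[3] - bbox[1] + 1)
    return RegionHomogeneity(sigma, n_edge, n_skin, extent)


def is_homogeneous(stats: RegionHomogeneity, params: HomogeneityParams | None = None) -> bool:
    """Evaluate the homogeneity criterion for one region (see module docstring)."""
    p = params or HomogeneityParams()
    sigma_ok = stats.sigma < p.sigma_max
    ratio_bbox_ok = stats.n_edge / stats.bbox_extent <= p.edge_bbox_max
    ratio_skin_ok = stats.n_edge / stats.n_skin <= p.edge_skin_max
    if p.grouped_or:
        return sigma_ok and (ratio_bbox_ok or ratio_skin_ok)
    return (sigma_ok and ratio_bbox_ok) or ratio_skin_ok


def iterate_refinement(
    spm: np.ndarray,
    params: HomogeneityParams | None = None,
    connectivity: int = 8,
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(threshold, mask)`` per iteration of the refinement loop.

    Each yielded mask has already had sub-``min_area`` regions removed.  The
    iterator stops after yielding the accepted mask (all regions homogeneous,
    vacuously so when none survive) or the empty mask forced once the
    threshold reaches ``t_cap``.
    """
    p = params or HomogeneityParams()
    spm = np.asarray(spm)
    norm = spm.astype(np.float64) / 255.0
    gradient = edge_magnitude(spm)
    structure = _structure(connectivity)

    t = p.t0
    while True:
        if t >= p.t_cap:
            yield t, np.zeros(spm.shape, dtype=bool)
            return
        mask = norm > t
        labeled, n = ndi.label(mask, structure=structure)
        if n:
            areas = np.bincount(labeled.ravel())
            keep = areas >= p.min_area
            keep[0] = False
            mask = keep[labeled]
            kept_labels = np.nonzero(keep)[0]
        else:
            kept_labels = np.array([], dtype=int)
        yield t, mask

        all_ok = True
        slices = ndi.find_objects(labeled)
        for lab in kept_labels:
            sl = slices[lab - 1]
            region = labeled[sl] == lab
            bbox = (sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1)
            stats = region_stats(
                spm[sl], region, bbox=bbox,
                sobel_threshold=p.sobel_threshold, gradient=gradient[sl],
            )
            if not is_homogeneous(stats, p):
                all_ok = False
                break
        if all_ok:
            return
        t *= p.growth


def homogeneity_refine(
    spm: np.ndarray,
    params: HomogeneityParams | None = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Run the refinement loop to acceptance and return the final mask."""
    mask = None
    for _, mask in iterate_refinement(spm, params, connectivity):
        pass
    assert mask is not None
    return mask
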