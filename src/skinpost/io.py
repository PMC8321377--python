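"""Raster I/O for skin probability maps (SPMs) and binary masks.

A skin probability map is a single-channel image whose pixel values encode a
detector's per-pixel skin score, rescaled to the integer range [0, 255].  On
disk both SPMs and masks are 8-bit grayscale PNG; masks use the polarity
skin = 255, nonskin = 0.  In memory an SPM is a 2-D ``uint8`` array and a
mask is a 2-D boolean array, mirroring the conventions of scikit-image.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "read_spm",
    "read_mask",
    "write_mask",
    "write_spm",
    "normalize_unit",
    "find_images",
]


def read_spm(path: str | Path) -> np.ndarray:
    """Read a skin probability map from an 8-bit grayscale image file.

    Multi-channel inputs are converted to luminance with a warning; the
    result is always a 2-D ``uint8`` array with values in [0, 255].

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    with Image.open(path) as img:
        if img.mode != "L":
            logger.warning(
                "%s has mode %s; converting to 8-bit luminance", path, img.mode
            )
            img = img.convert("L")
        arr = np.asarray(img, dtype=np.uint8)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{path} did not decode to a 2-D grayscale image")
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any pixel value above 127 counts as skin."""
    return read_spm(path) > 127


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 8-bit grayscale PNG (skin = 255, nonskin = 0)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    out = np.where(mask, 255, 0).astype(np.uint8)
    Image.fromarray(out, mode="L").save(Path(path))


def write_spm(spm: np.ndarray, path: str | Path) -> None:
    """Write an SPM as 8-bit grayscale PNG.

    Float inputs in [0, 1] (e.g. raw classifier scores) are rescaled by 255
    and rounded; integer inputs must already lie in [0, 255].
    """
    spm = np.asarray(spm)
    if spm.ndim != 2:
        raise ValueError("SPM must be 2-D")
    if np.issubdtype(spm.dtype, np.floating):
        if spm.min() < 0 or spm.max() > 1:
            raise ValueError("float SPM values must lie in [0, 1]")
        spm = np.round(spm * 255.0)
    if spm.min() < 0 or spm.max() > 255:
        raise ValueError("SPM values must lie in [0, 255]")
    Image.fromarray(spm.astype(np.uint8), mode="L").save(Path(path))


def normalize_unit(spm: np.ndarray) -> np.ndarray:
    """Map an 8-bit SPM onto [0, 1] by dividing by 255."""
    spm = np.asarray(spm)
    return spm.astype(np.float64) / 255.0


def find_images(directory: str | Path, pattern: str = "*.png") -> Sequence[Path]:
    """Glob a directory for raster files, sorted by filename for determinism."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    return sorted(directory.glob(pattern))
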