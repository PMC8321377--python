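"""Tri-level Otsu thresholding of a skin probability map.

The SPM is split into three probability sets — *low*, *discrete* (i.e.
intermediate), and *high* — by an exhaustive search for the threshold pair
``(t_low, t_high)`` that maximizes the between-class variance of the 256-bin
histogram, the natural multilevel generalization of Otsu's discriminant
criterion.  Only pixels in the *high* set are treated as skin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["TriLevelPartition", "otsu_three_class", "skin_mask", "LOW", "DISCRETE", "HIGH"]

LOW, DISCRETE, HIGH = 0, 1, 2


@dataclass
class TriLevelPartition:
    """A three-way partition of an SPM by two intensity thresholds.

    A pixel with value ``v`` is *low* when ``v <= t_low``, *high* when
    ``v > t_high`` (or ``v >= t_high`` when ``high_strict`` is False), and
    *discrete* otherwise.  ``labels`` stores the per-pixel codes
    ``LOW``/``DISCRETE``/``HIGH``.

    For degenerate (constant) inputs ``t_low`` may be -1 so that a constant
    value of 1 can still be labeled entirely *high*.
    """

    t_low: int
    t_high: int
    labels: np.ndarray
    high_strict: bool = True
    between_class_variance: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.t_low >= self.t_high:
            raise ValueError("t_low must be strictly below t_high")


def _between_class_variance_grid(hist: np.ndarray) -> np.ndarray:
    """Between-class variance for every ordered pair ``t_low < t_high``.

    Returns a 256x256 array indexed ``[t_low, t_high]``; invalid cells
    (``t_low >= t_high``) are ``-inf``.  Classes are the histogram slices
    ``[0, t_low]``, ``(t_low, t_high]``, ``(t_high, 255]``; an empty class
    contributes zero.
    """
    p = hist.astype(np.float64)
    p = p / p.sum()
    i = np.arange(256, dtype=np.float64)
    cum_w = np.cumsum(p)
    cum_m = np.cumsum(i * p)
    mean_total = cum_m[-1]

    t1 = np.arange(256)[:, None]
    t2 = np.arange(256)[None, :]
    w0, m0 = cum_w[t1], cum_m[t1]
    w1, m1 = cum_w[t2] - cum_w[t1], cum_m[t2] - cum_m[t1]
    w2, m2 = 1.0 - cum_w[t2], mean_total - cum_m[t2]

    def _term(w: np.ndarray, m: np.ndarray) -> np.ndarray:
        return np.where(w > 0, m * m / np.where(w > 0, w, 1.0), 0.0)

    var = _term(w0, m0) + _term(w1, m1) + _term(w2, m2) - mean_total**2
    var[t1 >= t2] = -np.inf
    return var


def otsu_three_class(spm: np.ndarray, high_strict: bool = True) -> TriLevelPartition:
    """Partition an SPM into low/discrete/high probability sets.

    The optimal ``(t_low, t_high)`` maximizes the three-class between-class
    variance over the 256-bin histogram; ties are broken by the smallest
    ``(t_low, t_high)`` in lexicographic order.

    A constant SPM has no discriminant structure: all pixels are assigned to
    a single set (*low* for value 0, *high* otherwise) with a warning.
    """
    spm = np.asarray(spm)
    if spm.ndim != 2:
        raise ValueError("SPM must be 2-D")
    if spm.min() < 0 or spm.max() > 255:
        raise ValueError("SPM values must lie in [0, 255]")
    values = spm.astype(np.uint8)
    hist = np.bincount(values.ravel(), minlength=256)

    if np.count_nonzero(hist) < 2:
        const = int(values.flat[0])
        logger.warning("constant SPM (value %d): degenerate partition", const)
        if const == 0:
            labels = np.full(spm.shape, LOW, dtype=np.uint8)
            return TriLevelPartition(0, 255, labels, high_strict)
        labels = np.full(spm.shape, HIGH, dtype=np.uint8)
        return TriLevelPartition(const - 2, const - 1, labels, high_strict)

    var = _between_class_variance_grid(hist)
    flat = int(np.argmax(var))  # first maximum = lexicographic smallest pair
    t_low, t_high = flat // 256, flat % 256

    labels = np.full(spm.shape, DISCRETE, dtype=np.uint8)
    labels[values <= t_low] = LOW
    if high_strict:
        labels[values > t_high] = HIGH
    else:
        labels[values >= t_high] = HIGH
    return TriLevelPartition(t_low, t_high, labels, high_strict, float(var[t_low, t_high]))


def skin_mask(partition: TriLevelPartition) -> np.ndarray:
    """Boolean mask of the *high* probability set (the detected skin)."""
    return partition.labels == HIGH
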