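"""Pixel-pooled segmentation scoring and method comparison.

Skin detection is scored with F1 = 2tp / (2tp + fn + fp) computed on pixel
counts *pooled* over a whole dataset (sum tp/fp/fn across images first, then
apply the formula).  Pooling makes the score independent of how pixels are
partitioned into images, unlike the per-image macro average, and therefore
insensitive to image-size variation within a dataset.  Method comparison
across datasets uses the Wilcoxon signed-rank test with an exact
sign-enumeration null for small samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PixelCounts",
    "confusion_counts",
    "pooled_f1",
    "pooled_precision_recall",
    "macro_f1",
    "report_table",
    "signed_rank_test",
    "grouped_eval",
]


@dataclass(frozen=True)
class PixelCounts:
    """Pixel-level confusion counts for one prediction/truth pair (skin = positive)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "PixelCounts") -> "PixelCounts":
        return PixelCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> PixelCounts:
    """Count tp/fp/fn/tn between a predicted and a ground-truth mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return PixelCounts(tp, fp, fn, tn)


def _as_pooled(counts: PixelCounts | Iterable[PixelCounts]) -> PixelCounts:
    if isinstance(counts, PixelCounts):
        return counts
    items = list(counts)
    if not items:
        raise ValueError("at least one PixelCounts required")
    total = items[0]
    for c in items[1:]:
        total = total + c
    return total


def pooled_f1(counts: PixelCounts | Iterable[PixelCounts]) -> float:
    """F1 of the summed pixel counts: 2tp / (2tp + fn + fp).

    When tp = fp = fn = 0 (perfect agreement on all-negative data) the score
    is defined as 1.0, with a log message since the value is conventional.
    """
    c = _as_pooled(counts)
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        logger.info("no positive pixels in prediction or truth; F1 defined as 1.0")
        return 1.0
    return 2 * c.tp / denom


def pooled_precision_recall(counts: PixelCounts | Iterable[PixelCounts]) -> tuple[float, float]:
    """Pooled precision and recall; each is 1.0 when its denominator is zero."""
    c = _as_pooled(counts)
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 1.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 1.0
    return precision, recall


def macro_f1(counts: Iterable[PixelCounts]) -> float:
    """Per-image F1 averaged over images (the alternative the pooled score avoids)."""
    items = list(counts)
    if not items:
        raise ValueError("at least one PixelCounts required")
    return float(np.mean([pooled_f1(c) for c in items]))


def report_table(
    results: Mapping[str, Mapping[str, float]],
    datasets: Sequence[str] | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Per-dataset F1 table with an ``Avg`` column per method.

    ``results`` maps method name -> {dataset name -> F1}.  ``Avg`` is the
    unweighted arithmetic mean over the dataset columns.  ``decimals``
    rounds for display (use 3 to mirror the conventional reporting
    precision); by default full precision is kept.

    Raises
    ------
    ValueError
        If any method is missing a value for any dataset.
    """
    if not results:
        raise ValueError("results must not be empty")
    if datasets is None:
        datasets = list(next(iter(results.values())).keys())
    rows = {}
    for method, values in results.items():
        missing = [d for d in datasets if d not in values]
        if missing:
            raise ValueError(f"method {method!r} is missing datasets {missing}")
        rows[method] = [float(values[d]) for d in datasets]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(datasets))
    table["Avg"] = table.mean(axis=1)
    if decimals is not None:
        table = table.round(decimals)
    table.index.name = "method"
    return table


def _exact_signed_rank_p(diffs: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p-value by enumerating all 2^n sign assignments.

    Works with tied magnitudes (average ranks) by doubling the ranks so the
    rank-sum support stays integral; the null distribution of the positive
    rank sum is built by dynamic programming, equivalent to full enumeration.
    """
    ranks2 = np.round(rankdata(np.abs(diffs)) * 2).astype(int)
    w_obs = int(ranks2[diffs > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    p_ge = float(dist[w_obs:].sum())
    p_le = float(dist[: w_obs + 1].sum())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def signed_rank_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon signed-rank p-value for paired scores ``a`` vs ``b``.

    Zero differences are dropped (Wilcoxon's convention).  For n <= 25
    retained pairs the p-value is exact, from full enumeration of the 2^n
    equally likely sign assignments; beyond that the normal approximation
    with tie correction is used.  ``alternative='greater'`` tests whether
    ``a`` tends to exceed ``b``.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 5 pairs, or all-zero differences.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D sequences of equal length")
    if a.size < 5:
        raise ValueError("at least 5 pairs required")
    diffs = a - b
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero; test undefined")

    n = diffs.size
    if n <= 25:
        return _exact_signed_rank_p(diffs, alternative)

    ranks = rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean_w) / np.sqrt(var_w)
    if alternative == "greater":
        return float(norm.sf(z))
    if alternative == "less":
        return float(norm.cdf(z))
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def grouped_eval(
    pairs: Iterable[tuple[np.ndarray, np.ndarray, Hashable]],
) -> tuple[dict[Hashable, float], float]:
    """Pool counts within groups (e.g. video id), then score per group.

    Returns ``(per_group_f1, mean_f1)`` where the mean is unweighted over
    groups; with a single group this reduces to :func:`pooled_f1`.
    """
    by_group: dict[Hashable, PixelCounts] = {}
    for pred, truth, key in pairs:
        c = confusion_counts(pred, truth)
        by_group[key] = by_group[key] + c if key in by_group else c
    if not by_group:
        raise ValueError("at least one (pred, truth, group) triple required")
    per_group = {k: pooled_f1(c) for k, c in by_group.items()}
    return per_group, float(np.mean(list(per_group.values())))
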