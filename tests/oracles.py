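"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as naive enumeration / flood fill /
direct transcription, sharing no code path with the package implementation.
"""

from itertools import product

import numpy as np

DEFAULT_THRESHOLDS = {
    "TS1": 0.12, "TS2": 0.1685, "TS3": 0.1685, "TB1": 1.0,
    "TL1": 3.5e-6, "TL2": 86.3e-6,
    "TR1": 0.9967, "TR2": 0.9995, "TR3": 0.9730, "TR4": 0.9992,
    "TR5": 0.9701, "TR6": 0.9979, "TR7": 0.8736, "TR8": 0.9984,
}


def decision_tree_reference(sr, cc, bsr, sr2, lrr, t=DEFAULT_THRESHOLDS):
    """Line-by-line transcription of the class-assignment pseudocode.

    The low-skin branch is an if/elif/else chain (a plain sequence of ifs
    would overwrite B with D); the border test is non-strict so that a
    fully skin-labeled border can reach G.  An image without regions is H.
    """
    if cc == 0:
        return "H"
    cls = "H"
    if sr > t["TS1"] and cc < 6:
        if bsr >= t["TB1"]:
            cls = "G"
    if (sr > t["TS2"]) and (cls != "G"):
        if cc == 1:
            if t["TL1"] <= lrr <= t["TL2"]:
                cls = "I"
            else:
                cls = "A"
        if cc == 2:
            if t["TR1"] <= sr2 <= t["TR2"]:
                cls = "I"
            else:
                cls = "A"
        if cc == 3:
            if t["TR3"] <= sr2 <= t["TR4"]:
                cls = "I"
            else:
                cls = "A"
        if cc == 4:
            if t["TR5"] <= sr2 <= t["TR6"]:
                cls = "K"
            else:
                cls = "C"
        if cc == 5:
            cls = "C"
        if cc in (6, 7):
            if t["TR7"] <= sr2 <= t["TR8"]:
                cls = "L"
            else:
                cls = "E"
        elif cc >= 8:
            cls = "E"
    if (sr < t["TS3"]) and (cls != "G"):
        if cc < 4:
            cls = "B"
        elif cc < 6:
            cls = "D"
        else:
            cls = "F"
    return cls


def flood_fill_label(mask, connectivity=8):
    """BFS connected-component labeling; returns (label_grid, count)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = [(r0, c0)]
                labels[r0, c0] = current
                while queue:
                    r, c = queue.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels, current


def erode_oracle(mask, radius):
    """Per-pixel check: the whole disk neighborhood must be skin and in-image."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    offs = [(dr, dc) for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1) if dr * dr + dc * dc <= radius ** 2]
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def dilate_oracle(mask, radius):
    """Per-pixel check: any in-image disk neighbor being skin suffices."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    offs = [(dr, dc) for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1) if dr * dr + dc * dc <= radius ** 2]
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def fill_holes_oracle(mask):
    """Background BFS from the image border (4-connectivity); the rest is filled."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    queue = []
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                queue.append((rr, cc))
    return mask | ~reach


def area_open_oracle(mask, min_count, connectivity=8):
    """Label with flood fill, then drop components with area < min_count."""
    labels, n = flood_fill_label(mask, connectivity)
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for lab in range(1, n + 1):
        component = labels == lab
        if component.sum() >= min_count:
            out |= component
    return out


def otsu_three_class_oracle(values):
    """Exhaustive search over all ordered threshold pairs.

    Maximizes the three-class between-class variance computed directly as
    sum_k w_k (mu_k - mu_total)^2 from histogram slices; first maximum in
    (t_low, t_high) lexicographic order wins.  Returns (t_low, t_high, var).
    """
    hist = np.bincount(np.asarray(values, dtype=np.uint8).ravel(), minlength=256)
    n = hist.sum()
    p = (hist / n).tolist()
    i_p = [i * pi for i, pi in enumerate(p)]
    cum_w = np.cumsum(p).tolist()
    cum_m = np.cumsum(i_p).tolist()
    mu_total = cum_m[-1]

    best = (-np.inf, None, None)
    for t1 in range(255):
        w0, m0 = cum_w[t1], cum_m[t1]
        v0 = w0 * (m0 / w0 - mu_total) ** 2 if w0 > 0 else 0.0
        for t2 in range(t1 + 1, 256):
            w1 = cum_w[t2] - w0
            m1 = cum_m[t2] - m0
            w2 = 1.0 - cum_w[t2]
            m2 = mu_total - cum_m[t2]
            var = v0
            if w1 > 0:
                var += w1 * (m1 / w1 - mu_total) ** 2
            if w2 > 0:
                var += w2 * (m2 / w2 - mu_total) ** 2
            if var > best[0]:
                best = (var, t1, t2)
    return best[1], best[2], best[0]


def wilcoxon_exact_oracle(diffs, alternative="greater"):
    """Exact signed-rank p-value by explicit enumeration of all sign patterns."""
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product((0, 1), repeat=n)
    ])
    eps = 1e-9
    p_ge = float(np.mean(ws >= w_obs - eps))
    p_le = float(np.mean(ws <= w_obs + eps))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))
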