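"""Independent brute-force reference implementations used only by the tests.

Each oracle computes the same quantity as the corresponding library routine
by direct enumeration, kept deliberately naive so that it cannot share a bug
with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import disk


def isodata_fixed_points(values: np.ndarray) -> list[float]:
    """All intermeans fixed points of a sample, by cut enumeration.

    A threshold T is a fixed point when T = (mean(v <= T) + mean(v > T)) / 2
    and T falls between the cut value and the next distinct value.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(v)
    out = []
    for i, c in enumerate(uniq[:-1]):
        lo = v[v <= c]
        hi = v[v > c]
        t = (lo.mean() + hi.mean()) / 2.0
        nxt = uniq[i + 1]
        if c <= t < nxt:
            out.append(float(t))
    return out


def max_entropy_naive(values: np.ndarray) -> int:
    """Kapur threshold for an integer-valued image by exhaustive search.

    Returns the integer T maximising H(<=T) + H(>T); foreground is > T.
    """
    v = np.asarray(values).ravel().astype(int)
    lo, hi = v.min(), v.max()
    counts = np.bincount(v - lo, minlength=hi - lo + 1)
    p = counts / counts.sum()
    best_t, best_h = None, -np.inf
    for t in range(hi - lo):  # split after value lo+t
        p1 = p[: t + 1]
        p2 = p[t + 1 :]
        w1, w2 = p1.sum(), p2.sum()
        if w1 <= 0 or w2 <= 0:
            continue
        q1 = p1[p1 > 0] / w1
        q2 = p2[p2 > 0] / w2
        h = -(q1 * np.log(q1)).sum() - (q2 * np.log(q2)).sum()
        if h > best_h:
            best_h, best_t = h, t
    assert best_t is not None
    return int(lo + best_t)


def bernsen_naive(image: np.ndarray, radius: int, contrast_threshold: float) -> np.ndarray:
    """Pixel-by-pixel Bernsen rule with symmetric (reflecting) edges."""
    arr = np.asarray(image, dtype=float)
    fp = disk(radius).astype(bool)
    padded = np.pad(arr, radius, mode="symmetric")
    out = np.zeros(arr.shape, dtype=bool)
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            win = padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1][fp]
            lo, hi = win.min(), win.max()
            if hi - lo >= contrast_threshold:
                out[r, c] = arr[r, c] > (hi + lo) / 2.0
    return out


def median_naive(image: np.ndarray, radius: int) -> np.ndarray:
    """Windowed median with a disk footprint and symmetric edges."""
    arr = np.asarray(image)
    fp = disk(radius).astype(bool)
    padded = np.pad(arr, radius, mode="symmetric")
    out = np.empty_like(arr)
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            win = padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1][fp]
            out[r, c] = np.median(win)
    return out


def distance_naive(mask: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the nearest True pixel, by full search."""
    mask = np.asarray(mask, dtype=bool)
    fg = np.argwhere(mask)
    out = np.zeros(mask.shape, dtype=float)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                continue
            d = np.hypot(fg[:, 0] - r, fg[:, 1] - c)
            out[r, c] = d.min()
    return out


def anova_f_naive(groups: list[np.ndarray]) -> tuple[float, tuple[int, int]]:
    """One-way ANOVA F statistic from the raw sum-of-squares decomposition."""
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_v) - len(groups)
    return float((ss_between / df_b) / (ss_within / df_w)), (df_b, df_w)


def paired_t_naive(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook paired t: mean(d) / (sd(d)/sqrt(n)), sample sd."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(d.size)))
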