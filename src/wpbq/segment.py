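"""Thresholding, mask processing and distance maps.

These are the primitives the automated distribution macro composes: an
iterative-intermeans ("Default") global threshold for the nucleus channel, a
Kapur maximum-entropy global threshold for the vesicle channels, the Bernsen
local threshold used for vesicle counting, a circular-window median filter,
binary watershed splitting of touching nuclei, and the Euclidean distance
map measured from the nucleus mask.

Conventions: global thresholds return a value T with foreground = pixels > T;
connected components are 8-connected; distances are kept as real values and
only clipped to 255 px for reporting parity with an 8-bit distance map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, h_maxima, local_maxima
from skimage.segmentation import watershed as _skimage_watershed

from . import defaults


class DegenerateInputError(ValueError):
    """Raised when an algorithm's input is degenerate (e.g. constant image)."""


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (px) to the nearest nucleus pixel.

    ``values`` holds unclipped real distances (0 on the nucleus mask);
    ``clipped`` reproduces the 8-bit 0-255 px range of the original macro's
    exported distance map.
    """

    values: np.ndarray
    nucleus_mask: np.ndarray
    clip_px: float = defaults.DISTANCE_CLIP_PX

    @property
    def clipped(self) -> np.ndarray:
        return np.minimum(self.values, self.clip_px)


def _check_nonconstant(channel: np.ndarray) -> np.ndarray:
    arr = np.asarray(channel, dtype=float)
    if arr.size == 0 or np.all(arr == arr.flat[0]):
        raise DegenerateInputError("constant or empty channel has no threshold")
    return arr


def threshold_isodata_default(channel: np.ndarray) -> float:
    """Iterative-intermeans threshold (ImageJ "Default"/isodata family).

    Starting from the global mean, iterate
    ``T <- (mean(values <= T) + mean(values > T)) / 2``
    to a fixed point.  Foreground is ``channel > T``.
    """
    arr = _check_nonconstant(channel).ravel()
    t = float(arr.mean())
    for _ in range(500):
        lo = arr[arr <= t]
        hi = arr[arr > t]
        if hi.size == 0:
            # T at or above max: step back below the maximum
            t = float(arr[arr < arr.max()].mean() + arr.max()) / 2.0
            continue
        if lo.size == 0:
            t = float(arr.min() + arr[arr > arr.min()].mean()) / 2.0
            continue
        t_new = (float(lo.mean()) + float(hi.mean())) / 2.0
        if t_new == t:
            return t
        t = t_new
    return t


def threshold_max_entropy(channel: np.ndarray, n_bins: int = 256) -> float:
    """Kapur maximum-entropy threshold.

    Maximises the sum of Shannon entropies of the below/above-threshold
    histogram classes.  Integer-valued images with range < ``n_bins`` use one
    bin per integer value (exact); otherwise the range is binned.  Returns
    the threshold as an intensity value; foreground is ``channel > T``.
    """
    arr = _check_nonconstant(channel).ravel()
    lo, hi = float(arr.min()), float(arr.max())
    integral = np.allclose(arr, np.round(arr))
    if integral and hi - lo < n_bins:
        edges = np.arange(np.floor(lo), np.floor(hi) + 2) - 0.5
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    hist, edges = np.histogram(arr, bins=edges)
    p = hist / hist.sum()

    P1 = np.cumsum(p)                       # mass of class <= bin t
    P2 = 1.0 - P1
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S1 = np.cumsum(plogp)
    S2 = S1[-1] - S1
    with np.errstate(divide="ignore", invalid="ignore"):
        H1 = np.where(P1 > 0, np.log(P1) - S1 / P1, -np.inf)
        H2 = np.where(P2 > 0, np.log(P2) - S2 / P2, -np.inf)
    # candidate split after bin t requires both classes non-empty
    valid = (P1 > 0) & (P2 > 0)
    total = np.where(valid, H1 + H2, -np.inf)
    best = total.max()
    if not np.isfinite(best):
        raise DegenerateInputError("no valid max-entropy split")
    # the cumulative-sum entropies carry ~1e-15 rounding; re-evaluate the
    # near-tied candidates directly and take the lowest maximising split
    candidates = np.flatnonzero(total >= best - 1e-6 * max(1.0, abs(best)))
    t_idx, best_h = -1, -np.inf
    for t in candidates:
        p1, p2 = p[: t + 1], p[t + 1 :]
        w1, w2 = p1.sum(), p2.sum()
        q1 = p1[p1 > 0] / w1
        q2 = p2[p2 > 0] / w2
        h = -(q1 * np.log(q1)).sum() - (q2 * np.log(q2)).sum()
        if h > best_h:
            best_h, t_idx = h, int(t)
    # threshold at the upper edge of the winning bin, so foreground = > T
    if integral and hi - lo < n_bins:
        return float(np.floor(lo) + t_idx)
    return float(edges[t_idx + 1])


def threshold_bernsen(
    channel: np.ndarray,
    radius_px: int = defaults.BERNSEN_RADIUS_PX,
    contrast_threshold: float = defaults.BERNSEN_CONTRAST,
) -> np.ndarray:
    """Bernsen local threshold over a circular window.

    For each pixel, with local min/max over the disk of ``radius_px``:
    if local contrast (max - min) >= ``contrast_threshold`` the pixel is
    foreground iff its value exceeds the local midgrey (max + min) / 2;
    low-contrast windows are wholly background.  Returns a boolean mask.
    """
    arr = np.asarray(channel, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(arr.shape):
        raise ValueError(
            f"Bernsen window (radius {radius_px}) larger than image {arr.shape}"
        )
    footprint = disk(radius_px)
    local_min = ndi.minimum_filter(arr, footprint=footprint, mode="reflect")
    local_max = ndi.maximum_filter(arr, footprint=footprint, mode="reflect")
    contrast = local_max - local_min
    midgrey = (local_max + local_min) / 2.0
    return (contrast >= contrast_threshold) & (arr > midgrey)


def median_filter(image: np.ndarray, radius_px: int = defaults.MEDIAN_RADIUS_PX) -> np.ndarray:
    """Median filter over a circular window with reflecting edges."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    footprint = disk(radius_px)
    if image.dtype == bool:
        out = ndi.median_filter(image.astype(np.uint8), footprint=footprint, mode="reflect")
        return out.astype(bool)
    return ndi.median_filter(image, footprint=footprint, mode="reflect")


def label_mask(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling (labels 1..n, 0 = background)."""
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    return labels, int(n)


def watershed_split(mask: np.ndarray, seed_h: float = 2.0) -> np.ndarray:
    """Split touching convex blobs along the ridge of the distance transform.

    Binary watershed: the mask's internal Euclidean distance transform is
    flooded from its regional maxima.  Maxima are extracted with an h-maxima
    tolerance ``seed_h`` (px) on a lightly smoothed EDT, so pixel-level
    boundary raggedness along a blob's medial ridge does not shatter one
    blob into several seeds, while the deep saddle between two genuinely
    touching blobs still separates them.  An empty mask yields an empty
    labelling.  Components are never merged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    edt = ndi.distance_transform_edt(mask)
    edt_s = ndi.gaussian_filter(edt, sigma=1.0)
    if seed_h > 0:
        seeds = h_maxima(edt_s, seed_h).astype(bool) & mask
    else:
        seeds = local_maxima(edt_s, connectivity=2) & mask
    # shallow components (EDT peak < seed_h) still need one seed each
    cc, n_cc = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    seeded = np.unique(cc[seeds])
    missing = np.setdiff1d(np.arange(1, n_cc + 1), seeded)
    if missing.size:
        for r, c in ndi.maximum_position(edt_s, cc, missing):
            seeds[r, c] = True
    markers, _ = ndi.label(seeds, structure=np.ones((3, 3), dtype=int))
    labels = _skimage_watershed(-edt_s, markers=markers, mask=mask, connectivity=2)
    # relabel sequentially 1..n
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    relabel = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    relabel[uniq] = np.arange(1, uniq.size + 1, dtype=np.int32)
    return relabel[labels]


def distance_map(nucleus_mask: np.ndarray, clip_px: float = defaults.DISTANCE_CLIP_PX) -> DistanceMap:
    """Euclidean distance map from the nucleus mask.

    Zero on nucleus pixels; elsewhere the exact Euclidean distance (px) to
    the nearest nucleus pixel.  Raises on an empty mask (no nucleus found).
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty nucleus mask: no nucleus found")
    values = ndi.distance_transform_edt(~mask)
    return DistanceMap(values=values, nucleus_mask=mask, clip_px=clip_px)


def nucleus_labels(
    nucleus_channel: np.ndarray,
    median_radius_px: int = defaults.MEDIAN_RADIUS_PX,
    apply_watershed: bool = True,
) -> np.ndarray:
    """Nucleus segmentation as used throughout the pipeline.

    Iterative-intermeans threshold, circular median filter to remove noise,
    then (by default) watershed splitting of touching nuclei.
    """
    t = threshold_isodata_default(nucleus_channel)
    mask = np.asarray(nucleus_channel, dtype=float) > t
    mask = median_filter(mask, median_radius_px)
    if apply_watershed:
        return watershed_split(mask)
    labels, _ = label_mask(mask)
    return labels
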