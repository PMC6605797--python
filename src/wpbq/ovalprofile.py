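"""Oval radial-sum intensity profile around the nucleus.

For classifying whether an overexpressed marker clusters perinuclearly: an
oval is fitted to the nucleus and enlarged by 20%, then for each of 360 ray
angles the interpolated pixel intensities are summed from the oval centre to
its boundary.  A perinuclear cluster on one side of the nucleus produces a
dominant angular peak; a homogeneous (cytosolic) distribution produces a
flat profile.  The peak/mean ratio of the (lightly smoothed) profile is the
classification statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from . import defaults
from .segment import label_mask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Oval:
    """Fitted nucleus ellipse after enlargement: centre (px), semi-axes (px),
    orientation in radians (angle of the major axis from the row axis,
    counter-clockwise; skimage regionprops convention)."""

    center: tuple[float, float]
    semi_major_px: float
    semi_minor_px: float
    orientation: float


@dataclass
class RadialProfile:
    """Per-ray radial intensity sums around an oval."""

    angles_deg: np.ndarray
    radial_sums: np.ndarray
    oval: Oval

    @property
    def total(self) -> float:
        return float(self.radial_sums.sum())


def fit_nucleus_oval(
    nucleus_mask: np.ndarray, enlargement: float = defaults.OVAL_ENLARGEMENT
) -> Oval:
    """Moment-based ellipse fit of the nucleus mask, axes scaled by 20%.

    If the mask has several components the largest is used (logged).
    """
    labels, n = label_mask(np.asarray(nucleus_mask, dtype=bool))
    if n == 0:
        raise ValueError("empty nucleus mask")
    props = regionprops(labels)
    if n > 1:
        log.warning("nucleus mask has %d components; using the largest", n)
        props = [max(props, key=lambda p: p.area)]
    p = props[0]
    return Oval(
        center=(float(p.centroid[0]), float(p.centroid[1])),
        semi_major_px=enlargement * p.axis_major_length / 2.0,
        semi_minor_px=enlargement * p.axis_minor_length / 2.0,
        orientation=float(p.orientation),
    )


def _boundary_radius(oval: Oval, angle_rad: float) -> float:
    """Distance from centre to the oval boundary along an image-frame ray.

    skimage's orientation is the angle between the row axis and the major
    axis, measured counter-clockwise with columns increasing to the right;
    a ray at image angle t has direction (cos t, sin t) in (row, col).
    """
    a, b = oval.semi_major_px, oval.semi_minor_px
    # regionprops: major-axis direction is (cos(orientation), sin(orientation))
    # in (row, col) up to sign, which the radius formula is insensitive to
    psi = angle_rad - oval.orientation
    denom = np.hypot(b * np.cos(psi), a * np.sin(psi))
    return a * b / denom


def radial_sum_profile(
    channel: np.ndarray, oval: Oval, n_rays: int = defaults.OVAL_N_RAYS
) -> RadialProfile:
    """Sum bilinearly interpolated intensities along each ray.

    Rays are equally spaced over 360 degrees; samples are taken at 1 px
    steps from the centre to the oval boundary (clipped to the image with a
    warning if the oval extends beyond it).
    """
    arr = np.asarray(channel, dtype=float)
    h, w = arr.shape
    cy, cx = oval.center
    angles = np.arange(n_rays) * (2 * np.pi / n_rays)
    if (
        cy - oval.semi_major_px < 0
        or cx - oval.semi_major_px < 0
        or cy + oval.semi_major_px > h - 1
        or cx + oval.semi_major_px > w - 1
    ):
        log.warning("oval extends beyond the image; rays are clipped")
    sums = np.zeros(n_rays)
    for i, t in enumerate(angles):
        r_max = _boundary_radius(oval, t)
        # epsilon guards the step count against float jitter in r_max
        n_steps = max(1, int(np.floor(r_max + 1e-9)) + 1)
        rr = np.arange(n_steps)
        ys = np.clip(cy + rr * np.cos(t), 0, h - 1)
        xs = np.clip(cx + rr * np.sin(t), 0, w - 1)
        vals = ndi.map_coordinates(arr, [ys, xs], order=1, mode="nearest")
        sums[i] = float(vals.sum())
    return RadialProfile(angles_deg=np.rad2deg(angles), radial_sums=sums, oval=oval)


def classify_clustering(
    profile: RadialProfile,
    peak_ratio_threshold: float = defaults.PEAK_RATIO_THRESHOLD,
    smooth_rays: int = defaults.OVAL_SMOOTH_RAYS,
) -> str:
    """'clustered' if the smoothed profile's max/mean >= threshold else
    'uniform'.

    The profile is smoothed with a circular moving average over
    ``smooth_rays`` rays so that single-vesicle spikes do not masquerade as
    a cluster; the ratio is scale-invariant.  Raises on an all-zero profile.
    """
    ratio = peak_ratio(profile, smooth_rays)
    return "clustered" if ratio >= peak_ratio_threshold else "uniform"


def _circular_smooth(sums: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return sums
    kernel = np.ones(window) / window
    n = len(sums)
    half = window // 2
    padded = np.concatenate([sums[-half:], sums, sums[:half]])
    return np.convolve(padded, kernel, mode="same")[half : half + n]


def peak_ratio(profile: RadialProfile, smooth_rays: int = defaults.OVAL_SMOOTH_RAYS) -> float:
    """The smoothed max/mean ratio used by :func:`classify_clustering`."""
    if profile.radial_sums.sum() <= 0:
        raise ValueError("zero-total profile cannot be classified")
    sums = _circular_smooth(profile.radial_sums, smooth_rays)
    return float(sums.max() / sums.mean())
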