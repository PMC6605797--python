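"""Vesicle counting and marker-positive cell counting.

Weibel-Palade bodies are segmented with a Bernsen local threshold (15 px
radius), size-filtered, and the object count normalised to the number of
nuclei in the image.  Cell "positivity" (does this cell contain any marker
vesicles?) is automated by assigning each detected particle to its nearest
nucleus - a proxy for the manual cell-counter reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import defaults
from .segment import label_mask, nucleus_labels, threshold_bernsen


@dataclass(frozen=True)
class CountResult:
    """Size-filtered particle count normalised per nucleus."""

    n_particles: int
    n_nuclei: int
    particles_per_nucleus: float
    size_filter_px: tuple[int, int | None]
    image_id: str = ""


def _filter_labels_by_area(labels: np.ndarray, min_area: int, max_area: int | None):
    n = int(labels.max())
    if n == 0:
        return labels, 0
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    keep = areas >= min_area
    if max_area is not None:
        keep &= areas <= max_area
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[1:][keep] = np.arange(1, keep.sum() + 1, dtype=np.int32)
    return lut[labels], int(keep.sum())


def detect_particles(
    vesicle_channel: np.ndarray,
    bernsen_radius: int = defaults.BERNSEN_RADIUS_PX,
    bernsen_contrast: float = defaults.BERNSEN_CONTRAST,
    min_area: int = defaults.COUNT_MIN_AREA_PX,
    max_area: int | None = defaults.COUNT_MAX_AREA_PX,
) -> tuple[np.ndarray, int]:
    """Bernsen mask -> 8-connected components -> area filter.

    Returns (labels relabelled 1..n, n).
    """
    mask = threshold_bernsen(vesicle_channel, bernsen_radius, bernsen_contrast)
    labels, _ = label_mask(mask)
    return _filter_labels_by_area(labels, min_area, max_area)


def count_wpbs(
    vesicle_channel: np.ndarray,
    nucleus_channel: np.ndarray,
    bernsen_radius: int = defaults.BERNSEN_RADIUS_PX,
    bernsen_contrast: float = defaults.BERNSEN_CONTRAST,
    size_filter_px: tuple[int, int | None] = (
        defaults.COUNT_MIN_AREA_PX,
        defaults.COUNT_MAX_AREA_PX,
    ),
    image_id: str = "",
) -> CountResult:
    """Count vesicles and normalise by the number of nuclei.

    Raises ``ValueError`` when no nucleus is found (the ratio is undefined).
    """
    if vesicle_channel.shape != nucleus_channel.shape:
        raise ValueError("channel shapes differ")
    min_area, max_area = size_filter_px
    _, n_particles = detect_particles(
        vesicle_channel, bernsen_radius, bernsen_contrast, min_area, max_area
    )
    nuclei = nucleus_labels(nucleus_channel)
    n_nuclei = int(nuclei.max())
    if n_nuclei == 0:
        raise ValueError("zero nuclei: particles-per-nucleus undefined")
    return CountResult(
        n_particles=n_particles,
        n_nuclei=n_nuclei,
        particles_per_nucleus=n_particles / n_nuclei,
        size_filter_px=size_filter_px,
        image_id=image_id,
    )


def count_positive_cells(
    vesicle_channel: np.ndarray,
    nucleus_label_img: np.ndarray,
    min_particles_per_cell: int = 1,
    bernsen_radius: int = defaults.BERNSEN_RADIUS_PX,
    bernsen_contrast: float = defaults.BERNSEN_CONTRAST,
    min_area: int = defaults.COUNT_MIN_AREA_PX,
) -> float:
    """Fraction of cells with >= ``min_particles_per_cell`` vesicles.

    Each detected particle is assigned to the nucleus nearest its centroid
    (Euclidean).  Requires a labelled nucleus image with >= 1 nucleus.
    """
    n_nuclei = int(nucleus_label_img.max())
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    labels, n_particles = detect_particles(
        vesicle_channel, bernsen_radius, bernsen_contrast, min_area, None
    )
    if n_particles == 0:
        return 0.0
    # nearest-nucleus label for every pixel via EDT feature transform
    _, (ir, ic) = ndi.distance_transform_edt(nucleus_label_img == 0, return_indices=True)
    nearest = nucleus_label_img[ir, ic]
    centroids = ndi.center_of_mass(
        np.ones_like(labels, dtype=float), labels, np.arange(1, n_particles + 1)
    )
    counts = np.zeros(n_nuclei + 1, dtype=int)
    for r, c in centroids:
        counts[nearest[int(round(r)), int(round(c))]] += 1
    positive = int((counts[1:] >= min_particles_per_cell).sum())
    return positive / n_nuclei
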