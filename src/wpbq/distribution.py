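"""Radial zone distribution of vesicle fluorescence (the core statistic).

For each image: segment the nuclei, build the Euclidean distance map, segment
each vesicle channel with a maximum-entropy threshold, and measure every
particle's minimum distance to the nucleus ("Distance (Min)") and integrated
intensity ("IntDen").  Particle intensities are binned into three radial
zones - perinuclear (<2 µm), intermediate (2-5 µm), periphery (>5 µm) - and
normalised by the total fluorescence of the image, so each zone fraction is
the share of the image's signal carried by vesicles at that distance from
the nucleus.  Images are averaged within a biological repeat, and repeats
summarised as mean ± SEM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import defaults
from .imgio import MultiChannelImage, estimate_background, subtract_background
from .segment import (
    DegenerateInputError,
    DistanceMap,
    distance_map,
    label_mask,
    nucleus_labels,
    threshold_max_entropy,
    watershed_split,
)

log = logging.getLogger(__name__)

ZONES = ("perinuclear", "intermediate", "periphery")

PARTICLE_COLUMNS = [
    "label", "min_distance_px", "min_distance_um", "integrated_intensity",
    "area_px", "centroid_row", "centroid_col", "zone",
]


@dataclass
class ZoneDistribution:
    """Per-image normalised intensity fractions in the three radial zones."""

    fractions: tuple[float, float, float]
    n_particles: tuple[int, int, int]
    image_id: str = ""

    def __post_init__(self) -> None:
        if any(f < -1e-12 or f > 1 + 1e-9 for f in self.fractions):
            raise ValueError(f"fractions out of [0,1]: {self.fractions}")
        if sum(self.fractions) > 1 + 1e-6:
            raise ValueError(f"fractions sum > 1: {self.fractions}")

    @property
    def total_fraction(self) -> float:
        return float(sum(self.fractions))


def measure_particles(
    labels: np.ndarray,
    channel: np.ndarray,
    dmap: DistanceMap,
    pixel_size_um: float,
    boundaries_um: tuple[float, float] = defaults.ZONE_BOUNDARIES_UM,
    use_centroid_distance: bool = False,
) -> pd.DataFrame:
    """Per-particle Distance (Min), IntDen, area, centroid and zone.

    ``labels`` is a labelled vesicle mask; intensities are summed over the
    (background-subtracted) ``channel``.  Distance is the minimum of the
    distance map over the particle's pixels, or the distance at the centroid
    when ``use_centroid_distance`` is set.
    """
    if labels.shape != channel.shape or labels.shape != dmap.values.shape:
        raise ValueError("labels, channel and distance map shapes differ")
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame(columns=PARTICLE_COLUMNS)
    idx = np.arange(1, n + 1)
    area = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, idx)
    intden = ndi.sum_labels(np.asarray(channel, dtype=float), labels, idx)
    mindist = ndi.minimum(dmap.values, labels, idx)
    centroids = ndi.center_of_mass(np.ones_like(labels, dtype=float), labels, idx)
    rows, cols = zip(*centroids)
    if use_centroid_distance:
        ri = np.clip(np.round(rows).astype(int), 0, labels.shape[0] - 1)
        ci = np.clip(np.round(cols).astype(int), 0, labels.shape[1] - 1)
        dist = dmap.values[ri, ci]
    else:
        dist = mindist
    dist_um = np.asarray(dist, dtype=float) * pixel_size_um
    zones = [assign_zone(d, 1.0, boundaries_um) for d in dist_um]
    return pd.DataFrame(
        {
            "label": idx,
            "min_distance_px": np.asarray(dist, dtype=float),
            "min_distance_um": dist_um,
            "integrated_intensity": np.asarray(intden, dtype=float),
            "area_px": area.astype(int),
            "centroid_row": rows,
            "centroid_col": cols,
            "zone": zones,
        }
    )


def assign_zone(
    distance: float,
    pixel_size_um: float,
    boundaries_um: tuple[float, float] = defaults.ZONE_BOUNDARIES_UM,
) -> str:
    """Zone of a nucleus distance: perinuclear <= 2 µm < intermediate <= 5 µm
    < periphery.  ``distance`` is in px and converted with ``pixel_size_um``
    (pass 1.0 for distances already in µm).  Boundary values go to the
    nearer-nucleus zone.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if distance < 0:
        raise ValueError("negative distance")
    d_um = distance * pixel_size_um
    lo, hi = boundaries_um
    if d_um <= lo:
        return ZONES[0]
    if d_um <= hi:
        return ZONES[1]
    return ZONES[2]


def zone_distribution(
    particles: pd.DataFrame, total_image_intensity: float, image_id: str = ""
) -> ZoneDistribution:
    """Normalise per-zone summed IntDen by the total image fluorescence."""
    if total_image_intensity <= 0:
        raise ValueError("total image intensity must be positive")
    fractions, counts = [], []
    for z in ZONES:
        sub = particles[particles.zone == z] if len(particles) else particles
        s = float(sub["integrated_intensity"].sum()) if len(particles) else 0.0
        fractions.append(s / total_image_intensity)
        counts.append(int(len(sub)) if len(particles) else 0)
    return ZoneDistribution(tuple(fractions), tuple(counts), image_id)


@dataclass
class GroupSummary:
    """Mean ± SEM of zone fractions across biological repeats."""

    group: str
    mean: dict[str, float]
    sem: dict[str, float]
    n_repeats: int
    n_images: int


def aggregate(distributions: pd.DataFrame, group: str = "") -> GroupSummary:
    """Hierarchical mean ± SEM: images are averaged within each repeat, then
    repeat means are averaged; SEM = sample sd of repeat means / sqrt(n).

    ``distributions`` needs columns ``repeat`` plus one column per zone.
    A single repeat yields SEM 0 (logged as degenerate).
    """
    if len(distributions) == 0:
        raise ValueError("empty group")
    per_repeat = distributions.groupby("repeat")[list(ZONES)].mean()
    n_rep = len(per_repeat)
    mean = per_repeat.mean()
    if n_rep < 2:
        log.warning("group %r has a single repeat; SEM reported as 0", group)
        sem = pd.Series(0.0, index=mean.index)
    else:
        sem = per_repeat.std(ddof=1) / np.sqrt(n_rep)
    return GroupSummary(
        group=group,
        mean={z: float(mean[z]) for z in ZONES},
        sem={z: float(sem[z]) for z in ZONES},
        n_repeats=n_rep,
        n_images=len(distributions),
    )


@dataclass
class DistributionResult:
    """Full per-image output of the radial distribution pipeline."""

    distributions: dict[str, ZoneDistribution]
    particles: dict[str, pd.DataFrame]
    dmap: DistanceMap = field(repr=False, default=None)
    nucleus_labels: np.ndarray = field(repr=False, default=None)
    total_intensity: dict[str, float] = field(default_factory=dict)


def run_distribution_pipeline(
    image: MultiChannelImage,
    nucleus_channel: str = "dapi",
    vesicle_channels: tuple[str, ...] | None = None,
    background_k: float = defaults.BACKGROUND_K,
    median_radius_px: int = defaults.MEDIAN_RADIUS_PX,
    nucleus_watershed: bool = True,
    vesicle_watershed: bool = False,
    boundaries_um: tuple[float, float] = defaults.ZONE_BOUNDARIES_UM,
    use_centroid_distance: bool = False,
) -> DistributionResult:
    """Run the automated radial-distribution analysis on one image.

    Stages: background subtraction of the vesicle channels, intermeans
    threshold + median filter (+ watershed) on the nucleus channel, distance
    map, maximum-entropy segmentation of each vesicle channel, per-particle
    measurement, zone binning and image-total normalisation.  Deterministic.
    """
    if nucleus_channel not in image.channels:
        raise KeyError(f"no nucleus channel {nucleus_channel!r} in image")
    if vesicle_channels is None:
        vesicle_channels = tuple(n for n in image.channels if n != nucleus_channel)
    if not vesicle_channels:
        raise ValueError("no vesicle channels to analyse")

    labels = nucleus_labels(
        image[nucleus_channel], median_radius_px, apply_watershed=nucleus_watershed
    )
    if labels.max() == 0:
        raise DegenerateInputError("nucleus segmentation found no nucleus")
    dmap = distance_map(labels > 0)

    distributions, particles, totals = {}, {}, {}
    for name in vesicle_channels:
        bg = estimate_background(image[name])
        chan = subtract_background(image[name], bg, background_k)
        total = float(chan.sum())
        if total <= 0:
            distributions[name] = ZoneDistribution((0.0, 0.0, 0.0), (0, 0, 0), name)
            particles[name] = pd.DataFrame(columns=PARTICLE_COLUMNS)
            totals[name] = 0.0
            continue
        try:
            t = threshold_max_entropy(chan)
        except DegenerateInputError:
            distributions[name] = ZoneDistribution((0.0, 0.0, 0.0), (0, 0, 0), name)
            particles[name] = pd.DataFrame(columns=PARTICLE_COLUMNS)
            totals[name] = total
            continue
        mask = chan > t
        if vesicle_watershed:
            ves_labels = watershed_split(mask)
        else:
            ves_labels, _ = label_mask(mask)
        table = measure_particles(
            ves_labels, chan, dmap, image.pixel_size_um, boundaries_um,
            use_centroid_distance,
        )
        particles[name] = table
        totals[name] = total
        distributions[name] = zone_distribution(table, total, name)
    return DistributionResult(
        distributions=distributions,
        particles=particles,
        dmap=dmap,
        nucleus_labels=labels,
        total_intensity=totals,
    )
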