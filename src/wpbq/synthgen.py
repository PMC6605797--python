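"""Synthetic endothelial-cell image generator with ground truth.

Renders multi-channel wide-field-like images of endothelial cells: a nucleus
channel with blurred elliptical nuclei and one or two vesicle channels with
diffraction-blurred spot- or rod-shaped secretory granules (Weibel-Palade
bodies are cigar-shaped, roughly 1-3 µm long).  Vesicles are placed at known
distances from the nucleus boundary so that every downstream measurement -
radial zone fractions, counts per nucleus, spot colocalization, angular
clustering - has an exact oracle.

Geometry is constructed analytically: a vesicle at distance d from the
nucleus is placed at boundary-point + d * outward-normal of the nucleus
ellipse, so its true distance (and hence true zone) is known by construction
rather than measured.  Vesicles are capsules (a segment of the configured
length, zero for spots, dilated to the configured radius) with a Gaussian
edge roll-off - the compact flat-topped profile that deconvolved wide-field
stacks show.  Rods lie tangentially to the nucleus by default, the
orientation cigar-shaped granules adopt when packed around the microtubule
organising centre, which also keeps their radial extent small and the zone
assignment unambiguous.

Zone placement uses the same 2 µm / 5 µm boundaries as the analysis, and the
placement margins guarantee that the minimum particle-to-nucleus distance
the pipeline measures falls in the same zone as the generator intended.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.special import erfc

from . import defaults
from .imgio import MultiChannelImage, write_image

ZONES = ("perinuclear", "intermediate", "periphery")


class PlacementError(RuntimeError):
    """Requested vesicle layout cannot be realised (zones too narrow, cells
    or vesicles that do not fit)."""


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic image.

    Intensity fractions in ``zone_intensity_fractions`` are fractions of the
    channel's total signal carried by vesicles in the perinuclear (<2 µm),
    intermediate (2-5 µm) and periphery (>5 µm) zones; any remainder is
    rendered as diffuse cytosolic signal.  A channel with no vesicles can
    still carry signal: ``diffuse_total_intensity`` sets the total diffuse
    mass for the pure-cytosolic phenotype.  ``coloc_fraction`` (used when
    two vesicle channels are configured) is the fraction of second-channel
    spots placed exactly at first-channel spot centres.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = defaults.PIXEL_SIZE_UM
    bit_depth: int = 16
    n_cells: int = 2
    nucleus_axes_um: tuple[float, float] = (7.0, 5.0)
    nucleus_intensity: float = 3000.0
    n_vesicles_per_cell: int = 40
    vesicle_shape: str = "rod"  # "spot" | "rod"
    vesicle_length_um: float = 1.5
    vesicle_radius_um: float = 0.45
    vesicle_sigma_um: float = 0.15
    vesicle_peak_intensity: float = 3000.0
    rod_orientation: str = "tangential"  # "tangential" | "random"
    zone_intensity_fractions: tuple[float, float, float] = (0.25, 0.35, 0.30)
    cluster_sector_deg: float | None = None
    periphery_max_um: float = 8.5
    nucleus_channel: str = "dapi"
    vesicle_channels: tuple[str, ...] = ("vwf",)
    channel_offsets_um: tuple[float, float] = (0.0, 0.0)
    coloc_fraction: float = 0.0
    coloc_exclusion_um: float = 1.2
    min_separation_um: float | None = None
    diffuse_total_intensity: float | None = None
    background_level: float = 100.0
    noise_sd: float = 20.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.zone_intensity_fractions
        if len(f) != 3 or any(x < 0 or x > 1 for x in f) or sum(f) > 1 + 1e-9:
            raise ValueError("zone_intensity_fractions must be in [0,1] and sum <= 1")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        for name in ("pixel_size_um", "vesicle_length_um", "vesicle_sigma_um",
                     "vesicle_radius_um", "periphery_max_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.nucleus_axes_um) <= 0:
            raise ValueError("nucleus_axes_um must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.vesicle_shape not in ("spot", "rod"):
            raise ValueError("vesicle_shape must be 'spot' or 'rod'")
        if self.n_vesicles_per_cell > 0 and sum(f) <= 0:
            raise ValueError("vesicles requested but all zone fractions are zero")

    @property
    def snr(self) -> float:
        """Peak vesicle intensity over background read-noise sd."""
        return np.inf if self.noise_sd == 0 else self.vesicle_peak_intensity / self.noise_sd


@dataclass
class GroundTruth:
    """Generator-side record of everything the pipeline should recover.

    ``vesicles``: one row per vesicle (channel, cell, row/col in px,
    distance_um from the nucleus boundary, zone, intensity = total rendered
    photon mass, pair = row index of the first-channel partner for
    colocalized second-channel spots, else -1).
    ``cells``: nucleus centre (px), semi-axes (µm) and orientation (rad).
    ``total_signal``: per-channel total signal mass (vesicles + diffuse),
    the denominator of the true zone fractions.
    """

    vesicles: pd.DataFrame
    cells: pd.DataFrame
    total_signal: dict[str, float]
    zone_fractions: dict[str, tuple[float, float, float]]
    clustered: bool
    config: SyntheticConfig = field(repr=False, default=None)

    def recompute_zone_fractions(self, channel: str) -> tuple[float, float, float]:
        """Zone fractions recomputed from the per-vesicle records."""
        ves = self.vesicles[self.vesicles.channel == channel]
        total = self.total_signal[channel]
        return tuple(
            float(ves.loc[ves.zone == z, "intensity"].sum() / total) for z in ZONES
        )

    def coloc_pairs(self) -> pd.DataFrame:
        """Second-channel vesicles placed on first-channel centres."""
        return self.vesicles[self.vesicles.pair >= 0]


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse_point_normal(center, axes, theta, phi):
    """Boundary point and outward unit normal of a rotated ellipse.

    ``axes`` = (a, b) semi-axes, ``theta`` = rotation, ``phi`` = boundary
    parameter.  Works in (row, col) coordinates.
    """
    a, b = axes
    ct, st = np.cos(theta), np.sin(theta)
    # unrotated boundary point and normal direction
    py, px = a * np.cos(phi), b * np.sin(phi)
    ny, nx = np.cos(phi) / a, np.sin(phi) / b
    # rotate into image frame
    ry = center[0] + ct * py - st * px
    rx = center[1] + st * py + ct * px
    gy = ct * ny - st * nx
    gx = st * ny + ct * nx
    norm = np.hypot(gy, gx)
    return (ry, rx), (gy / norm, gx / norm)


def _ellipse_mask(shape, center, axes_px, theta):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dy + st * dx
    v = -st * dy + ct * dx
    a, b = axes_px
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _render_vesicle(image, center, sigma_px, length_px, radius_px, direction, mass):
    """Add one vesicle; returns the rendered mass (= ``mass`` when the patch
    fits inside the frame).

    The vesicle body is a line segment of ``length_px`` (a point for spots)
    dilated to ``radius_px`` - a capsule - with a Gaussian edge roll-off of
    ``sigma_px``.  This flat-topped profile models the compact structures
    that iterative deconvolution produces from wide-field stacks; a pure
    Gaussian would put a large share of its mass into threshold-clipped
    tails, which deconvolved vesicle images do not show.
    """
    r = int(np.ceil(radius_px + 4 * sigma_px + length_px / 2)) + 1
    cy, cx = int(round(center[0])), int(round(center[1]))
    y0, y1 = max(0, cy - r), min(image.shape[0], cy + r + 1)
    x0, x1 = max(0, cx - r), min(image.shape[1], cx + r + 1)
    if y0 >= y1 or x0 >= x1:
        return 0.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - center[0]
    dx = xx - center[1]
    # distance to the central segment (projection clamped to +/- L/2)
    t = np.clip(dy * direction[0] + dx * direction[1], -length_px / 2, length_px / 2)
    dist = np.hypot(dy - t * direction[0], dx - t * direction[1])
    patch = 0.5 * erfc((dist - radius_px) / (sigma_px * np.sqrt(2.0)))
    total = patch.sum()
    if total <= 0:
        return 0.0
    patch *= mass / total
    image[y0:y1, x0:x1] += patch
    return float(mass)


def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items by non-negative weights."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        return np.zeros_like(w, dtype=int)
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return counts


# ---------------------------------------------------------------------------

def _place_cells(cfg: SyntheticConfig, rng: np.random.Generator):
    """Nucleus centres, orientations; guarantees non-overlapping territories."""
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    a_um = max(cfg.nucleus_axes_um)
    reach_um = a_um + cfg.periphery_max_um
    border_px = reach_um / px + 6  # vesicle patches must stay inside the frame
    min_sep_px = 2 * reach_um / px
    lo_y, hi_y = border_px, h - border_px
    lo_x, hi_x = border_px, w - border_px
    if hi_y <= lo_y or hi_x <= lo_x:
        raise PlacementError(
            f"image {cfg.image_size_px} too small for nuclei with "
            f"{reach_um:.1f} µm reach at {px} µm/px"
        )
    # restart the whole layout when it runs into a geometric dead end
    # (e.g. a first nucleus dead-centre leaves no room for a second)
    centers: list[tuple[float, float]] = []
    for _restart in range(500):
        centers = []
        for _ in range(cfg.n_cells):
            for _attempt in range(100):
                cand = (rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x))
                if all(
                    np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep_px
                    for c in centers
                ):
                    centers.append(cand)
                    break
            else:
                break
        if len(centers) == cfg.n_cells:
            break
    else:
        raise PlacementError(
            f"could not place {cfg.n_cells} non-overlapping cells in "
            f"{cfg.image_size_px} image"
        )
    thetas = rng.uniform(0, np.pi, size=cfg.n_cells)
    return centers, thetas


def _zone_bands(cfg: SyntheticConfig) -> list[tuple[float, float]]:
    """Feasible centroid-distance band (µm) per zone after safety margins.

    The inner margin keeps the minimum pixel distance of the rendered,
    segmented vesicle inside the intended zone; the outer margin only keeps
    it within the cell's reach.
    """
    inward = cfg.vesicle_radius_um + 3 * cfg.vesicle_sigma_um
    if cfg.vesicle_shape == "rod" and cfg.rod_orientation == "random":
        inward += cfg.vesicle_length_um / 2
    m_in = inward + 0.4  # + discretisation slack (~1 px)
    lo_b, hi_b = defaults.ZONE_BOUNDARIES_UM
    bands = [
        (inward + 0.15, lo_b - 0.1),
        (lo_b + m_in, hi_b - 0.1),
        (hi_b + m_in, cfg.periphery_max_um),
    ]
    return bands


def generate_image(config: SyntheticConfig) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one multi-channel image and its ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    pixels and ground truth.  Raises :class:`PlacementError` when the
    requested geometry cannot be realised.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    sigma_px = cfg.vesicle_sigma_um / px
    radius_px = cfg.vesicle_radius_um / px
    length_px = cfg.vesicle_length_um / px if cfg.vesicle_shape == "rod" else 0.0

    centers, thetas = _place_cells(cfg, rng)
    axes_px = (cfg.nucleus_axes_um[0] / px, cfg.nucleus_axes_um[1] / px)

    nucleus_mask = np.zeros((h, w), dtype=bool)
    cells_rows = []
    for i, (c, th) in enumerate(zip(centers, thetas)):
        nucleus_mask |= _ellipse_mask((h, w), c, axes_px, th)
        cells_rows.append(
            {"cell": i, "row": c[0], "col": c[1],
             "semi_major_um": cfg.nucleus_axes_um[0],
             "semi_minor_um": cfg.nucleus_axes_um[1], "orientation": th}
        )

    bands = _zone_bands(cfg)
    fracs = np.asarray(cfg.zone_intensity_fractions, dtype=float)
    zone_counts = _apportion(cfg.n_vesicles_per_cell, fracs)
    for z, (n_z, f_z, (lo, hi)) in enumerate(zip(zone_counts, fracs, bands)):
        if n_z > 0 and lo >= hi:
            raise PlacementError(
                f"zone '{ZONES[z]}' band [{lo:.2f}, {hi:.2f}] µm is empty for "
                f"this vesicle geometry; cannot place vesicles at fraction {f_z}"
            )

    sector = None
    if cfg.cluster_sector_deg is not None:
        half = np.deg2rad(cfg.cluster_sector_deg) / 2
        sector_centers = rng.uniform(0, 2 * np.pi, size=cfg.n_cells)
        sector = [(c - half, c + half) for c in sector_centers]

    def sample_position(cell_i, zone_i):
        lo, hi = bands[zone_i]
        d_um = rng.uniform(lo, hi)
        if sector is None:
            phi = rng.uniform(0, 2 * np.pi)
        else:
            phi = rng.uniform(*sector[cell_i])
        (ry, rx), (ny, nx) = _ellipse_point_normal(
            centers[cell_i], axes_px, thetas[cell_i], phi
        )
        pos = (ry + d_um / px * ny, rx + d_um / px * nx)
        if cfg.vesicle_shape == "rod" and cfg.rod_orientation == "tangential":
            direction = (-nx, ny)
        elif cfg.vesicle_shape == "rod":
            ang = rng.uniform(0, np.pi)
            direction = (np.cos(ang), np.sin(ang))
        else:
            direction = (0.0, 1.0)
        return pos, d_um, direction

    min_sep_px = (cfg.min_separation_um / px) if cfg.min_separation_um else 0.0

    def sample_separated(cell_i, zone_i, placed):
        """sample_position with a same-channel minimum-separation constraint."""
        if min_sep_px <= 0:
            return sample_position(cell_i, zone_i)
        for _attempt in range(500):
            pos, d_um, direction = sample_position(cell_i, zone_i)
            if not placed or np.min(
                np.hypot(np.asarray(placed)[:, 0] - pos[0],
                         np.asarray(placed)[:, 1] - pos[1])
            ) >= min_sep_px:
                return pos, d_um, direction
        raise PlacementError(
            f"cannot keep vesicles {cfg.min_separation_um} µm apart in zone "
            f"'{ZONES[zone_i]}'"
        )

    # channel A layout, reused for colocalized channel-B spots
    signal = {name: np.zeros((h, w)) for name in cfg.vesicle_channels}
    ves_rows = []
    # unit-mass kernel peak: probe the kernel once
    probe = np.zeros((int(2 * radius_px + 8 * sigma_px + length_px) + 9,) * 2)
    c0 = (probe.shape[0] - 1) / 2
    _render_vesicle(probe, (c0, c0), sigma_px, length_px, radius_px, (0.0, 1.0), 1.0)
    unit_peak = float(probe.max())
    mass = cfg.vesicle_peak_intensity / unit_peak

    a_records: dict[int, list[int]] = {i: [] for i in range(cfg.n_cells)}
    placed_a: list[tuple[float, float]] = []
    for ci in range(cfg.n_cells):
        for zi, n_z in enumerate(zone_counts):
            for _ in range(n_z):
                pos, d_um, direction = sample_separated(ci, zi, placed_a)
                placed_a.append(pos)
                rendered = _render_vesicle(
                    signal[cfg.vesicle_channels[0]], pos, sigma_px, length_px,
                    radius_px, direction, mass,
                )
                ves_rows.append(
                    {"channel": cfg.vesicle_channels[0], "cell": ci,
                     "row": pos[0], "col": pos[1], "distance_um": d_um,
                     "zone": ZONES[zi], "intensity": rendered, "pair": -1}
                )
                a_records[ci].append(len(ves_rows) - 1)

    if len(cfg.vesicle_channels) >= 2:
        bname = cfg.vesicle_channels[1]
        off = (cfg.channel_offsets_um[0] / px, cfg.channel_offsets_um[1] / px)
        a_all = [idx for lst in a_records.values() for idx in lst]
        n_b = cfg.n_vesicles_per_cell * cfg.n_cells
        n_coloc = int(round(cfg.coloc_fraction * n_b))
        n_coloc = min(n_coloc, len(a_all))
        coloc_idx = rng.choice(len(a_all), size=n_coloc, replace=False) if n_coloc else []
        chosen = [a_all[i] for i in np.sort(np.asarray(coloc_idx, dtype=int))]
        a_pos = np.array([[ves_rows[i]["row"], ves_rows[i]["col"]] for i in a_all]) \
            if a_all else np.zeros((0, 2))
        excl_px = cfg.coloc_exclusion_um / px

        for idx in chosen:
            arow = ves_rows[idx]
            pos = (arow["row"] + off[0], arow["col"] + off[1])
            direction = (0.0, 1.0)
            if cfg.vesicle_shape == "rod":
                direction = rng.standard_normal(2)
                direction /= np.hypot(*direction)
            rendered = _render_vesicle(signal[bname], pos, sigma_px, length_px,
                                       radius_px, direction, mass)
            ves_rows.append(
                {"channel": bname, "cell": arow["cell"], "row": pos[0],
                 "col": pos[1], "distance_um": arow["distance_um"],
                 "zone": arow["zone"], "intensity": rendered, "pair": idx}
            )
        # independent (non-colocalized) B spots, kept clear of A centres
        n_free = n_b - len(chosen)
        per_cell = _apportion(n_free, np.ones(cfg.n_cells))
        for ci in range(cfg.n_cells):
            z_counts = _apportion(per_cell[ci], fracs)
            for zi, n_z in enumerate(z_counts):
                for _ in range(n_z):
                    for _attempt in range(400):
                        pos, d_um, direction = sample_position(ci, zi)
                        if a_pos.size == 0 or np.min(
                            np.hypot(a_pos[:, 0] - pos[0], a_pos[:, 1] - pos[1])
                        ) >= excl_px:
                            break
                    else:
                        raise PlacementError(
                            "cannot place non-colocalized spot clear of driver spots"
                        )
                    rendered = _render_vesicle(signal[bname], pos, sigma_px,
                                               length_px, radius_px, direction, mass)
                    ves_rows.append(
                        {"channel": bname, "cell": ci, "row": pos[0],
                         "col": pos[1], "distance_um": d_um, "zone": ZONES[zi],
                         "intensity": rendered, "pair": -1}
                    )

    vesicles = pd.DataFrame(
        ves_rows,
        columns=["channel", "cell", "row", "col", "distance_um", "zone",
                 "intensity", "pair"],
    )

    # diffuse cytosolic remainder
    f_diffuse = 1.0 - float(fracs.sum())
    total_signal = {}
    for name in cfg.vesicle_channels:
        v_mass = float(vesicles.loc[vesicles.channel == name, "intensity"].sum())
        if fracs.sum() > 0 and v_mass > 0:
            s_total = v_mass / float(fracs.sum())
        elif cfg.diffuse_total_intensity is not None:
            s_total = cfg.diffuse_total_intensity
        else:
            s_total = v_mass
        d_mass = s_total - v_mass
        if d_mass > 1e-9:
            cyto = np.zeros((h, w), dtype=bool)
            reach_px = (max(cfg.nucleus_axes_um) + cfg.periphery_max_um) / px
            for c, th in zip(centers, thetas):
                cyto |= _ellipse_mask((h, w), c, (reach_px, reach_px), th)
            cyto &= ~nucleus_mask
            layer = np.where(cyto, d_mass / cyto.sum(), 0.0)
            signal[name] += ndi.gaussian_filter(layer, sigma=2.0)
        total_signal[name] = s_total

    zone_fractions = {}
    for name in cfg.vesicle_channels:
        ves = vesicles[vesicles.channel == name]
        tot = total_signal[name]
        zone_fractions[name] = tuple(
            float(ves.loc[ves.zone == z, "intensity"].sum() / tot) if tot > 0 else 0.0
            for z in ZONES
        )

    # render nucleus channel and apply noise last
    nucleus_signal = ndi.gaussian_filter(
        nucleus_mask.astype(float) * cfg.nucleus_intensity, sigma=1.0
    )
    max_val = 2**cfg.bit_depth - 1
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    channels: dict[str, np.ndarray] = {}
    for name, sig in [(cfg.nucleus_channel, nucleus_signal)] + [
        (n, signal[n]) for n in cfg.vesicle_channels
    ]:
        img = sig + cfg.background_level
        if cfg.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        channels[name] = np.clip(np.round(img), 0, max_val).astype(dtype)

    image = MultiChannelImage(
        channels=channels, pixel_size_um=px, bit_depth=cfg.bit_depth,
        provenance={"generator": "wpbq.synthgen", "seed": cfg.seed},
    )
    gt = GroundTruth(
        vesicles=vesicles,
        cells=pd.DataFrame(cells_rows),
        total_signal=total_signal,
        zone_fractions=zone_fractions,
        clustered=cfg.cluster_sector_deg is not None,
        config=cfg,
    )
    return image, gt


def generate_group(
    config: SyntheticConfig,
    n_images: int,
    n_repeats: int,
    out_dir: str | Path,
    group: str = "group",
    seed: int | None = None,
) -> pd.DataFrame:
    """Write a condition's worth of images to disk with one ground-truth CSV.

    Layout: ``out_dir/group/repeat_i/image_j.tif`` plus
    ``out_dir/group/ground_truth.csv`` and the config as YAML.  Per-image
    seeds are derived deterministically from ``seed`` (default: the config
    seed).  Returns a manifest DataFrame (path, group, repeat, image); the
    manifest CSV stores image paths relative to its own directory, so a
    generated dataset can be moved or compared as a tree.
    """
    if n_images < 1 or n_repeats < 1:
        raise ValueError("n_images and n_repeats must be >= 1")
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_repeats * n_images)

    root = Path(out_dir) / group
    root.mkdir(parents=True, exist_ok=True)
    manifest_rows, gt_frames = [], []
    k = 0
    for rep in range(1, n_repeats + 1):
        rep_dir = root / f"repeat_{rep}"
        rep_dir.mkdir(exist_ok=True)
        for im in range(1, n_images + 1):
            cfg_i = dataclasses.replace(config, seed=int(child_seeds[k]))
            k += 1
            image, gt = generate_image(cfg_i)
            path = rep_dir / f"image_{im}.tif"
            write_image(path, image)
            tab = gt.vesicles.copy()
            tab.insert(0, "image", im)
            tab.insert(0, "repeat", rep)
            tab.insert(0, "group", group)
            gt_frames.append(tab)
            manifest_rows.append(
                {"path": str(path.relative_to(root)), "group": group,
                 "repeat": rep, "image": im, "seed": int(child_seeds[k - 1])}
            )
    pd.concat(gt_frames, ignore_index=True).to_csv(root / "ground_truth.csv", index=False)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict = {k_: (list(v) if isinstance(v, tuple) else v) for k_, v in cfg_dict.items()}
    (root / "config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest
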