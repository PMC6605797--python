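"""Image input and background subtraction.

Images are multi-channel wide-field micrographs stored as multi-page TIFFs
(one page per channel).  Channels are split on load and each marker channel
is background-subtracted before any measurement: the background level is
estimated from a region of interest that contains no cells, the mean is
subtracted from the whole image, and pixels indistinguishable from the
background are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import defaults


@dataclass
class MultiChannelImage:
    """Named 2-D channels with a shared pixel calibration.

    Attributes
    ----------
    channels : dict of str -> ndarray
        Per-channel pixel grids, all the same shape.
    pixel_size_um : float
        Lateral calibration in micrometres per pixel.
    bit_depth : int
        Nominal bit depth of the acquisition (8 or 16).
    provenance : dict
        Free-form origin record (path, group, repeat).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 16
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean/sd of a background region of interest.

    ``roi`` is ``(row0, col0, row1, col1)`` with exclusive upper bounds.
    ``sd`` is the population standard deviation of the ROI pixels.
    """

    roi: tuple[int, int, int, int]
    mean: float
    sd: float


def read_image(
    path: str | Path,
    channel_names: list[str] | tuple[str, ...],
    pixel_size_um: float = defaults.PIXEL_SIZE_UM,
) -> MultiChannelImage:
    """Read a multi-page TIFF into named channels.

    Raises ``ValueError`` if the page count does not match ``channel_names``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected 2-D pages, got array of shape {data.shape}")
    if data.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: {data.shape[0]} pages but {len(channel_names)} "
            f"channel names {tuple(channel_names)}"
        )
    bit_depth = 8 if data.dtype == np.uint8 else 16
    channels = {name: data[i].copy() for i, name in enumerate(channel_names)}
    return MultiChannelImage(
        channels=channels,
        pixel_size_um=pixel_size_um,
        bit_depth=bit_depth,
        provenance={"path": str(path)},
    )


def write_image(path: str | Path, image: MultiChannelImage) -> None:
    """Write channels as a multi-page TIFF, channel names in page metadata."""
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={"channels": names, "pixel_size_um": image.pixel_size_um},
    )


def find_background_roi(
    channel: np.ndarray, tile_px: int = defaults.BACKGROUND_TILE_PX
) -> tuple[int, int, int, int]:
    """Automatic background ROI: the lowest-mean ``tile_px`` square tile.

    Tiles are placed on a half-tile stride grid; the tile with the lowest
    mean intensity is taken as cell-free background.  A fallback for when no
    manual ROI is supplied.
    """
    h, w = channel.shape
    tile = min(tile_px, h, w)
    stride = max(1, tile // 2)
    best = None
    best_mean = np.inf
    for r0 in range(0, h - tile + 1, stride):
        for c0 in range(0, w - tile + 1, stride):
            m = float(channel[r0 : r0 + tile, c0 : c0 + tile].mean())
            if m < best_mean:
                best_mean = m
                best = (r0, c0, r0 + tile, c0 + tile)
    assert best is not None
    return best


def estimate_background(
    channel: np.ndarray, roi: tuple[int, int, int, int] | None = None
) -> BackgroundEstimate:
    """Mean and population sd of the background ROI pixels."""
    if roi is None:
        roi = find_background_roi(channel)
    r0, c0, r1, c1 = roi
    h, w = channel.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} outside image of shape {channel.shape}")
    patch = np.asarray(channel[r0:r1, c0:c1], dtype=float)
    if patch.size == 0:
        raise ValueError("empty background ROI")
    return BackgroundEstimate(roi=roi, mean=float(patch.mean()), sd=float(patch.std()))


def subtract_background(
    channel: np.ndarray,
    bg: BackgroundEstimate,
    similarity_k: float = defaults.BACKGROUND_K,
) -> np.ndarray:
    """Background-subtract a channel.

    Pixels within ``similarity_k * bg.sd`` of the background mean are first
    replaced by the mean (so they land exactly on zero), then the mean is
    subtracted everywhere and the result clamped at zero.  Returns float64.
    """
    out = np.asarray(channel, dtype=float).copy()
    similar = np.abs(out - bg.mean) <= similarity_k * bg.sd
    out[similar] = bg.mean
    out -= bg.mean
    np.clip(out, 0.0, None, out=out)
    return out
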