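"""Central registry of analysis defaults.

Every tunable that the original ImageJ/ICY workflow left implicit lives here,
so a run's effective configuration can be audited in one place.  All values
are plain module constants; the CLI serialises the effective set next to its
outputs.
"""

#: Pixel calibration (µm per pixel) assumed for 40x wide-field images when the
#: input carries none.  Always overridable; never hard-coded downstream.
PIXEL_SIZE_UM = 0.3

#: Background similarity factor k: pixels within k*sd of the background-ROI
#: mean count as "similar to the background" and are zeroed by subtraction.
BACKGROUND_K = 2.0

#: Side length (px) of the automatic background ROI (lowest-mean tile).
BACKGROUND_TILE_PX = 64

#: Bernsen local threshold: window radius (px) and minimum local contrast.
#: Contrast is in intensity units of the processed channel.
BERNSEN_RADIUS_PX = 15
BERNSEN_CONTRAST = 15.0

#: Median filter radius (px) applied to the nucleus mask.
MEDIAN_RADIUS_PX = 2

#: Radial zone boundaries (µm from the nucleus edge):
#: perinuclear <= 2, intermediate (2, 5], periphery > 5.
ZONE_BOUNDARIES_UM = (2.0, 5.0)

#: Distance-map values are clipped at 255 px for reporting parity with the
#: original 8-bit distance map; binning uses unclipped distances.
DISTANCE_CLIP_PX = 255.0

#: Particle size filter for vesicle counting (px); max_area=None is unbounded.
COUNT_MIN_AREA_PX = 4
COUNT_MAX_AREA_PX = None

#: Spot detection: threshold multiplier on the robust noise level of the
#: band-pass response.
SPOT_SENSITIVITY = 5.0

#: Detection spot sizes (px diameter): WPBs ~14 px, small Rab46 puncta 4-7 px.
SPOT_SIZE_WPB_PX = 14
SPOT_SIZE_SMALL_PX = 5

#: Oval-profile parameters: nucleus ellipse enlargement, number of rays, and
#: angular smoothing window (rays) applied before the peak/mean ratio.
OVAL_ENLARGEMENT = 1.2
OVAL_N_RAYS = 360
OVAL_SMOOTH_RAYS = 15

#: Peak/mean ratio above which a radial profile counts as "clustered".
PEAK_RATIO_THRESHOLD = 2.0

#: Significance tiers: *, **, *** at these p-value cut-offs.
SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001)


def as_dict() -> dict:
    """All defaults as a plain dict (for logging / YAML dumps)."""
    return {
        k: v
        for k, v in globals().items()
        if k.isupper() and not k.startswith("_")
    }
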