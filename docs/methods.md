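# Methods

This note records the models, algorithmic conventions and design choices
behind `wpbq`, in the order the pipeline applies them, together with what the
synthetic validation does and does not establish.

## Background subtraction

The background level of each marker channel is estimated from a cell-free
region of interest (user-supplied rectangle, or automatically the
lowest-mean 64×64 tile on a half-tile grid).  Pixels within `k·sd` of the
ROI mean are treated as indistinguishable from background and set to the
mean, then the mean is subtracted everywhere and the result clamped at zero.

* `k = 2` by default (`defaults.BACKGROUND_K`).  "Similar to the background"
  has no canonical definition; two population standard deviations keeps
  ~95% of pure-background pixels at exactly zero while touching little real
  signal at high SNR.
* Replace-then-subtract (rather than subtract-then-replace) was chosen so
  that background-like pixels land exactly on zero; the two orders are
  otherwise equivalent up to the clamp.  The operation is idempotent once the
  ROI is fully zeroed.
* Consequence worth knowing: the replacement erodes genuine signal that sits
  within `k·sd` of background.  At SNR ≳ 100 this is negligible; below
  SNR ≈ 50 it visibly biases intensity-weighted statistics (see
  *Validation*, below).

## Segmentation primitives

* **Nucleus threshold** — iterative intermeans (the isodata family):
  starting from the global mean, `T ← (mean(v ≤ T) + mean(v > T))/2` to a
  fixed point; foreground is `v > T`.  Computed on raw values, not a
  256-bin histogram, so the fixed point is exact.
* **Vesicle threshold** — Kapur maximum entropy: the threshold maximising
  the summed Shannon entropies of the below/above histogram classes.
  Integer images with range < 256 use one bin per grey value (exact);
  near-tied candidates are re-evaluated with the direct per-class entropy
  formula and the lowest maximiser is taken, which makes the argmax robust
  to the ~1e−15 rounding of the cumulative-sum evaluation.
* **Bernsen local threshold** (counting only): circular window of radius
  15 px; where local contrast `max−min` is at least 15 intensity units the
  pixel is compared with the local midgrey, otherwise the window is
  assigned to background.  The contrast threshold is expressed in units of
  the processed channel and is configurable; 15 is the common default for
  8-bit data and transfers unchanged to background-subtracted data whose
  noise floor is small.
* **Median filter** — circular footprint, reflecting edges.
* **Watershed split** — binary watershed of the internal Euclidean distance
  transform.  Seeds are regional maxima of the lightly smoothed (σ = 1 px)
  EDT extracted with an h-maxima tolerance of 2 px: boundary raggedness on
  a noisy nucleus mask otherwise shatters the medial ridge into several
  maxima and over-splits single nuclei, while the saddle between two
  genuinely touching nuclei is far deeper than 2 px and still separates.
  Components whose EDT peak is below the tolerance keep one seed each, so
  the operation never merges and never drops components.
* **Distance map** — exact Euclidean distance to the nearest nucleus pixel,
  zero on the mask.  Distances are kept as real values; a 0–255 px clipped
  view is provided for parity with 8-bit distance-map exports, but binning
  always uses the unclipped values.
* Connectivity is 8-connected throughout.

## Radial zone statistic

Zone boundaries are 2 µm and 5 µm from the nucleus edge, with boundary
values assigned to the nearer-nucleus zone (measure-zero at float
precision; fixed for reproducibility).  Distances are converted from px
with a mandatory `pixel_size_um` (default 0.3 µm/px, plausible for 40×
wide-field; every interface lets the caller override it, and a
`--bins-px` compatibility mode accepts bin edges directly in px).
A particle's distance is the minimum of the distance map over its pixels;
binning by centroid distance is available as an option.  "Total fluorescence
of the image" is the sum of the background-subtracted vesicle channel, so
the three zone fractions sum to the segmented share of the image's signal
and are invariant under positive scaling of the channel.

Aggregation is hierarchical: fractions are averaged over the images of a
biological repeat, and the group summary is the mean ± SEM (sample sd, n−1)
of the repeat means.  A single repeat reports SEM 0 with a logged warning.

## Counting and positivity

Counting applies Bernsen, 8-connected labelling and an area filter
(default min 4 px, no upper bound — excludes single-pixel noise and keeps
rods).  The ratio to the nucleus count requires at least one nucleus.  The
marker-positive-cell fraction assigns each detected particle to the nucleus
nearest its centroid (EDT feature transform) — an automated proxy for a
manual cell-counter reading, and documented as such.

## Spot detection and colocalization

The detector is a scale-normalised negative Laplacian of Gaussian at
σ = spot_size/(2√2), local maxima with non-maximum suppression at half the
spot size, quadratic sub-pixel refinement, and a threshold of
`sensitivity × 1.4826·MAD` of the response (sensitivity 5 by default), with
a floor of 2% of the strongest response so the noise-free limit does not
detect numerical ripple.  It is a faithful stand-in for wavelet/band-pass
spot detectors; reproducing any specific plugin's internals is a non-goal.

Colocalization is object-based: candidate (driver, secondary) pairs within
the match radius are matched closest-first, each spot used at most once.
The match radius defaults to half the driver spot size.  The reported
percentage divides by the secondary count by default (the share of
secondary-marker puncta residing on driver structures); the denominator is
switchable to the driver count.

## Oval profile and clustering classification

The nucleus mask's moment ellipse (largest component if several) is
enlarged by 20%; along each of 360 rays, bilinearly interpolated
intensities are sampled at 1 px steps from centre to the ellipse boundary
and summed.  The classifier smooths the profile with a circular 15-ray
moving average and calls a distribution "clustered" when max/mean ≥ 2.0.
The smoothing window and ratio are tool parameters, not claims: the ratio
is scale-invariant, the smoothing prevents a single punctum from
masquerading as a cluster, and on the synthetic reference conditions the
two classes separate by a factor ≳ 5 (clustered ratios ≳ 7, diffuse ≲ 1.6),
so the verdict is insensitive to the exact threshold.  Whether to sample to
the oval boundary or a fixed radius was open; the boundary was chosen so
the profile covers the same cytoplasmic shell at every angle.

## Statistics

Paired t on differences; one-way ANOVA with Bonferroni-adjusted pairwise t
tests (p × number of comparisons, capped at 1); two-way ANOVA with
interaction restricted to complete balanced layouts, which makes the
sum-of-squares decomposition unambiguous.  Degenerate inputs follow logged
conventions: identical paired samples give t = 0, p = 1; zero-variance
non-zero differences give p = 0.  Tiers: * p < 0.05, ** p < 0.01,
*** p < 0.001.

## Synthetic data: what it emulates

One image is 256×256 px at 0.3 µm/px, 16-bit, with two non-overlapping
cells (elliptical nuclei, semi-axes 7×5 µm, random orientation).  Vesicles
are capsules — a line segment (1.5 µm for rods, a point for spots) dilated
to 0.45 µm radius with a Gaussian edge roll-off of 0.15 µm — rendered with
exactly known total intensity (peak 3000 counts by default).  The capsule
profile models the compact, flat-topped structures that iterative
deconvolution produces from wide-field stacks; a pure Gaussian would carry
a large share of its mass in tails that any threshold clips, which
deconvolved vesicle images do not show.  Rods lie tangentially to the
nucleus by default (the packing orientation around the microtubule
organising centre), keeping their radial extent small.

Placement is analytic: a vesicle at distance d sits at
boundary-point + d·(outward normal) of its nucleus ellipse, so its true
distance and zone are known by construction.  Placement bands include an
inner safety margin (vesicle radius + 3σ + ~1 px) so the *minimum* pixel
distance the pipeline measures stays in the intended zone.  Zone counts
follow largest-remainder apportionment of the configured intensity
fractions; any remainder of the unit intensity budget is rendered as
smooth diffuse cytosolic signal, and a channel can be made purely diffuse
(the cytosolic-phenotype control).  Optional features: angular sector
clustering (the perinuclear-cluster phenotype), a same-channel minimum
separation (resolvable-object conditions for counting), a second channel
with a configured fraction of spots placed exactly on first-channel
centres (non-colocalized spots are kept ≥ 1.2 µm from any driver), and a
lateral channel offset.  Noise — optional Poisson, then Gaussian read
noise — is applied last, after the ground truth is frozen.

What it does **not** emulate: optical anisotropy and depth effects, uneven
illumination, autofluorescence texture, touching cells, vesicle brightness
heterogeneity, or chromatic misregistration beyond a rigid offset.  Passing
the validation therefore shows the *measurement chain* is correct, not that
segmentation thresholds are optimal for any particular real dataset.

## Validation design and problem sizes

The standard scenarios live in `wpbq.validation` and are exercised both by
`tests/test_acceptance.py` and `scripts/acceptance.py`:

* **Primitive/oracle agreement** — 100 random images ≤ 32×32 px; isodata
  (fixed-point enumeration), Kapur (exhaustive search), Bernsen
  (pixel-by-pixel rule), distance map (nearest-pixel search): exact match.
* **Zone-fraction recovery** — 20 matched image pairs, clustered
  (0.8/0.1/0.05) vs dispersed (0.2/0.3/0.4) spot-vesicle populations at the
  default acquisition (peak 3000, read noise 20, SNR 150): mean absolute
  error ≤ 0.05 per zone (measured ≈ 0.02, a small negative bias from the
  sub-threshold rim of each vesicle), and the clustered perinuclear
  fraction exceeds the dispersed one in every pair.
* **Count recovery** — 10 images of 25 rods/cell, ≥ 3.5 µm apart, SNR 10,
  size class 10 px (half the ~20 px rod footprint): within ±5%.
* **Colocalization recovery** — true fractions 0/0.25/0.5/1 over 20 seeds
  at SNR 10: within ±5 points, exact at the noise-free extremes.
* **Clustering classification** — 20 sector-clustered + 20 diffuse images:
  ≥ 95% agreement with ground truth.
* **ANOVA calibration** — 1,000 null simulations of three groups × six
  repeat-level fractions: rejection rate 5% ± 1.5% at α = 0.05.
  Simulating at the fraction level (rather than rendering thousands of
  images) tests exactly the quantity the ANOVA consumes while keeping the
  check fast.
* **Determinism** — regenerating a dataset with the same seed yields
  byte-identical trees; re-running the pipeline on the same image yields
  identical fractions.

Problem sizes were chosen so the full validation runs in well under a
minute of CPU while keeping every tolerance comfortably non-trivial.

## Known limitations

* Intensity-fraction recovery degrades below SNR ≈ 50: the `k·sd`
  background replacement and the entropy threshold together discard the
  dim rim of each vesicle, and the lost share grows with the noise floor
  (MAE ≈ 0.07 at SNR 50, ≈ 0.30 at SNR 10 for a 0.8 perinuclear fraction).
  Detection-based readouts (counts, spot colocalization) remain accurate
  at SNR 10.  For low-SNR data, lower `k` and inspect the
  `effective_config.yaml` record.
* Particles are assigned to the nearest nucleus, not to their parent cell;
  in dense multi-cell fields a peripheral vesicle of one cell may bin
  against a neighbouring nucleus.
* Touching vesicles merge into one particle unless the vesicle-channel
  watershed is enabled; counting accuracy presumes resolvable objects.
* The two-way ANOVA supports balanced designs only.
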