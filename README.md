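# wpbq — Weibel–Palade body quantification

`wpbq` quantifies the intracellular trafficking of secretory vesicles —
chiefly Weibel–Palade bodies (WPBs), the cigar-shaped vWF-storage granules of
endothelial cells — from multi-channel wide-field fluorescence images.  It is
aimed at cell biologists who currently run this analysis as a chain of
ImageJ/Fiji and ICY plugin steps and want the same measurements as a scripted,
tested, reproducible pipeline.

## What it measures

**Radial zone distribution (the core readout).** A nucleus mask is built from
the DAPI channel with an iterative-intermeans ("Default") threshold, cleaned
with a circular median filter and split by a binary watershed.  The Euclidean
distance map `D(x) = min_{y ∈ nucleus} ‖x − y‖` is computed from the mask.
Each vesicle channel is background-subtracted, segmented with a Kapur
maximum-entropy threshold, and every particle *i* is measured for its minimum
nucleus distance `d_i = min_{x ∈ i} D(x)` ("Distance (Min)") and integrated
intensity `IntDen_i = Σ_{x ∈ i} I(x)`.  Particle intensities are binned into
three zones

| zone | distance from nucleus |
|---|---|
| perinuclear | d ≤ 2 µm |
| intermediate | 2 µm < d ≤ 5 µm |
| periphery | d > 5 µm |

and the per-zone sums are normalised by the total fluorescence of the image,
so each zone fraction `f_z = Σ_{i ∈ z} IntDen_i / Σ_x I(x)` is the share of a
cell population's signal at that distance from the nucleus.  Fractions are
averaged per image, then per biological repeat, and reported as mean ± SEM
across repeats.

**Counting.** WPBs per nucleus via a Bernsen local threshold (15 px radius),
8-connected components, a size filter, and normalisation by the nucleus count;
plus an automated marker-positive-cell fraction by nearest-nucleus assignment.

**Colocalization.** Scale-matched Laplacian-of-Gaussian spot detection in two
channels and object-based matching with a driver-channel convention (a green
spot counts only if it falls within a match radius of an unclaimed red spot).

**Oval profile.** A moment-fitted nucleus ellipse enlarged by 20%, a 360-ray
radial-sum intensity profile, and a peak/mean-ratio classifier separating
perinuclear clustering from homogeneous cytosolic signal.

**Statistics.** Paired t tests, one-/two-way ANOVA with Bonferroni post hoc,
and the conventional significance tiers (*, **, *** at p < 0.05, 0.01, 0.001).

**Synthetic ground truth.** Because every one of these measurements is easy to
get subtly wrong, `wpbq.synthgen` renders synthetic endothelial-cell images —
elliptical nuclei, capsule-shaped vesicles placed at exactly known distances,
zones, intensities and co-spot pairings, configurable noise — so the whole
pipeline is validated end-to-end against known answers (see
`docs/methods.md`).

## Worked example

Generate two synthetic conditions — a perinuclear-clustered population (80% of
signal within 2 µm of the nucleus) and a dispersed one — and run the radial
distribution analysis:

```bash
cat > clustered.yaml <<'YAML'
zone_intensity_fractions: [0.8, 0.1, 0.05]
vesicle_shape: spot
YAML
cat > dispersed.yaml <<'YAML'
zone_intensity_fractions: [0.2, 0.3, 0.4]
vesicle_shape: spot
YAML
wpbq synth --out data --group clustered --n-images 3 --n-repeats 3 --seed 1 --config clustered.yaml
wpbq synth --out data --group dispersed --n-images 3 --n-repeats 3 --seed 2 --config dispersed.yaml
# join the two manifests (path,group,repeat,...) and analyse
wpbq distribution --manifest manifest.csv --out results
```

`results/group_summary.csv` then contains:

```
group,channel,zone,mean,sem,n_repeats,n_images
clustered,vwf,perinuclear,0.7843720832994926,0.001740180167863149,3,9
clustered,vwf,intermediate,0.09015534948386256,0.0001740015062281083,3,9
clustered,vwf,periphery,0.04511687724710114,0.00023530572860278468,3,9
dispersed,vwf,perinuclear,0.20294783418929283,0.000362396788334089,3,9
dispersed,vwf,intermediate,0.29333609313781,0.0003616812586147012,3,9
dispersed,vwf,periphery,0.4054095945963356,0.000352234991661828,3,9
```

The clustered condition's perinuclear fraction (0.784 ± 0.002, mean ± SEM over
3 repeats of 3 images) recovers the configured 0.8 to within the segmentation
rim loss; the dispersed condition recovers 0.20/0.29/0.41 against a configured
0.2/0.3/0.4.  `results/per_image.csv` holds the per-image fractions,
`results/particles.csv` every particle's distance and IntDen, and
`results/effective_config.yaml` all parameters in effect.

The other subcommands (`wpbq count`, `wpbq coloc`, `wpbq ovalprofile`,
`wpbq stats`, `wpbq report`) follow the same pattern; `--help` lists their
options.

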