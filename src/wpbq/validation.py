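"""End-to-end validation scenarios on synthetic ground truth.

Each function generates a standard synthetic study condition, runs the
corresponding analysis stage, and returns the recovery statistics.  The
conditions are fixed properties of the validation design (sample sizes,
zone-fraction layouts, acquisition parameters); only the master seed varies.

All sub-seeds are derived deterministically from the master seed and stay
below 2**31.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np

from .coloc import coloc_analysis
from .counting import count_wpbs
from .distribution import run_distribution_pipeline
from .imgio import estimate_background, subtract_background
from .ovalprofile import classify_clustering, fit_nucleus_oval, radial_sum_profile
from .segment import nucleus_labels
from .stats import one_way_anova
from .synthgen import SyntheticConfig, generate_group, generate_image

#: Radial layouts of the two reference conditions: a perinuclear-clustered
#: cell population versus a dispersed one.
CLUSTERED_FRACTIONS = (0.8, 0.1, 0.05)
UNIFORM_FRACTIONS = (0.2, 0.3, 0.4)

#: Acquisition for intensity-based recovery: the generator default, a bright
#: deconvolved-wide-field-like regime (peak/noise-sd = 150).
RECOVERY_NOISE_SD = 20.0
RECOVERY_BACKGROUND = 100.0

#: Acquisition for detection-based recovery (counting, spot coloc): SNR 10.
DETECTION_NOISE_SD = 300.0
DETECTION_BACKGROUND = 1000.0


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def zone_fraction_recovery(seed: int = 0, n_images: int = 20) -> dict:
    """Recover known radial zone fractions through the full pipeline.

    Renders ``n_images`` matched image pairs (same layout seed) for the
    clustered and uniform conditions and reports the mean absolute error of
    the recovered fractions per zone, plus how often the clustered
    condition's perinuclear fraction exceeds the uniform one within a
    matched pair.
    """
    seeds = _child_seeds(seed, n_images)
    errors = {"clustered": [], "uniform": []}
    peri = {"clustered": [], "uniform": []}
    for s in seeds:
        for name, fractions in (
            ("clustered", CLUSTERED_FRACTIONS),
            ("uniform", UNIFORM_FRACTIONS),
        ):
            cfg = SyntheticConfig(
                seed=int(s),
                vesicle_shape="spot",
                zone_intensity_fractions=fractions,
                noise_sd=RECOVERY_NOISE_SD,
                background_level=RECOVERY_BACKGROUND,
            )
            image, truth = generate_image(cfg)
            res = run_distribution_pipeline(image)
            measured = np.array(res.distributions["vwf"].fractions)
            expected = np.array(truth.zone_fractions["vwf"])
            errors[name].append(measured - expected)
            peri[name].append(measured[0])
    mae = {k: np.abs(np.array(v)).mean(axis=0) for k, v in errors.items()}
    pairs_ok = sum(
        c > u for c, u in zip(peri["clustered"], peri["uniform"])
    )
    return {
        "mae_clustered": tuple(mae["clustered"]),
        "mae_uniform": tuple(mae["uniform"]),
        "max_mae": float(max(mae["clustered"].max(), mae["uniform"].max())),
        "monotone_pairs": pairs_ok,
        "n_pairs": n_images,
        "mean_peri_clustered": float(np.mean(peri["clustered"])),
        "mean_peri_uniform": float(np.mean(peri["uniform"])),
    }


def count_recovery(seed: int = 0, n_images: int = 10) -> dict:
    """Recover vesicles-per-nucleus by Bernsen counting at SNR 10.

    Rod-shaped vesicles placed at least 3.5 µm apart (resolvable objects;
    merged rods are a segmentation limit, not a counting one), no diffuse
    component, 25 per cell in 2 cells.
    """
    rel_errors = []
    for s in _child_seeds(seed, n_images):
        cfg = SyntheticConfig(
            seed=int(s),
            vesicle_shape="rod",
            n_vesicles_per_cell=25,
            min_separation_um=3.5,
            zone_intensity_fractions=(0.3, 0.4, 0.3),
            noise_sd=DETECTION_NOISE_SD,
            background_level=DETECTION_BACKGROUND,
        )
        image, truth = generate_image(cfg)
        channel = subtract_background(
            image["vwf"], estimate_background(image["vwf"])
        )
        # size class for rod-shaped objects: half the ~20 px rod footprint,
        # which rejects the few-pixel noise clumps that survive Bernsen
        res = count_wpbs(channel, image["dapi"], size_filter_px=(10, None))
        expected = len(truth.vesicles) / cfg.n_cells
        rel_errors.append(res.particles_per_nucleus / expected - 1.0)
    rel = np.array(rel_errors)
    return {
        "max_abs_relative_error": float(np.abs(rel).max()),
        "mean_relative_error": float(rel.mean()),
        "n_images": n_images,
    }


def coloc_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0),
) -> dict:
    """Recover configured colocalization fractions from two-channel images.

    SNR-10 images with 25 spots per cell per channel; spot size 5 px in both
    channels.  Also runs the noise-free extremes, which must be exact.
    """
    out: dict = {"per_fraction": {}}
    seeds = _child_seeds(seed, n_seeds)
    worst = 0.0
    for frac in fractions:
        errs = []
        for s in seeds:
            cfg = SyntheticConfig(
                seed=int(s),
                vesicle_shape="spot",
                vesicle_channels=("vwf", "rab46"),
                coloc_fraction=frac,
                n_vesicles_per_cell=25,
                min_separation_um=2.0,
                noise_sd=DETECTION_NOISE_SD,
                background_level=DETECTION_BACKGROUND,
            )
            image, _ = generate_image(cfg)
            res = coloc_analysis(image["vwf"], image["rab46"], 5, 5)
            errs.append(res.percent_coloc - 100.0 * frac)
        errs = np.array(errs)
        out["per_fraction"][frac] = {
            "mean_percent": 100.0 * frac + float(errs.mean()),
            "max_abs_error": float(np.abs(errs).max()),
        }
        worst = max(worst, float(np.abs(errs).max()))
    exact = {}
    for frac in (0.0, 1.0):
        cfg = SyntheticConfig(
            seed=int(seeds[0]),
            vesicle_shape="spot",
            vesicle_channels=("vwf", "rab46"),
            coloc_fraction=frac,
            n_vesicles_per_cell=25,
            min_separation_um=2.0,
            noise_sd=0.0,
        )
        image, _ = generate_image(cfg)
        exact[frac] = coloc_analysis(image["vwf"], image["rab46"], 5, 5).percent_coloc
    out["max_abs_error"] = worst
    out["noise_free"] = exact
    return out


def classification_accuracy(seed: int = 0, n_images: int = 40) -> dict:
    """Classify perinuclear-clustered versus cytosolic marker distributions.

    Half the images carry 90% of the signal in a 60-degree perinuclear
    sector (the clustered phenotype); half carry purely diffuse cytosolic
    signal (the homogeneous phenotype).  Returns the agreement with ground
    truth of the oval-profile peak-ratio classifier.
    """
    n_half = n_images // 2
    seeds = _child_seeds(seed, n_images)
    correct = 0
    for i, s in enumerate(seeds):
        clustered = i < n_half
        if clustered:
            cfg = SyntheticConfig(
                seed=int(s), image_size_px=(160, 160), n_cells=1,
                vesicle_shape="spot", n_vesicles_per_cell=30,
                zone_intensity_fractions=(0.9, 0.0, 0.0),
                cluster_sector_deg=60.0,
                noise_sd=RECOVERY_NOISE_SD, background_level=RECOVERY_BACKGROUND,
            )
        else:
            cfg = SyntheticConfig(
                seed=int(s), image_size_px=(160, 160), n_cells=1,
                n_vesicles_per_cell=0, zone_intensity_fractions=(0.0, 0.0, 0.0),
                diffuse_total_intensity=1.0e6,
                noise_sd=RECOVERY_NOISE_SD, background_level=RECOVERY_BACKGROUND,
            )
        image, _ = generate_image(cfg)
        labels = nucleus_labels(image["dapi"])
        oval = fit_nucleus_oval(labels > 0)
        channel = subtract_background(
            image["vwf"], estimate_background(image["vwf"])
        )
        profile = radial_sum_profile(channel, oval)
        verdict = classify_clustering(profile)
        correct += verdict == ("clustered" if clustered else "uniform")
    return {"accuracy": correct / n_images, "n_images": n_images}


def anova_type_i_rate(seed: int = 0, n_sims: int = 1000, alpha: float = 0.05) -> dict:
    """Type-I error of the one-way ANOVA under the null.

    Each simulation draws three groups of six repeat-level zone fractions
    from the same distribution (mean 0.3, sd 0.05, the scale of perinuclear
    fractions across biological repeats) and tests at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        groups = {g: rng.normal(0.3, 0.05, size=6) for g in ("a", "b", "c")}
        rejections += one_way_anova(groups).p_value < alpha
    return {"type_i_rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        h.update(path.relative_to(root).as_posix().encode())
        h.update(path.read_bytes())
    return h.hexdigest()


def determinism_check(seed: int = 0, workdir: str | Path | None = None) -> dict:
    """Re-run generation and analysis with the same seed; outputs must be
    byte-identical."""
    import tempfile

    cfg = SyntheticConfig(seed=seed, n_vesicles_per_cell=10)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        generate_group(cfg, n_images=2, n_repeats=2, out_dir=tmp / "a", seed=seed)
        generate_group(cfg, n_images=2, n_repeats=2, out_dir=tmp / "b", seed=seed)
        identical_files = _tree_digest(tmp / "a") == _tree_digest(tmp / "b")
    image, _ = generate_image(dataclasses.replace(cfg, seed=seed + 1))
    a = run_distribution_pipeline(image).distributions["vwf"].fractions
    b = run_distribution_pipeline(image).distributions["vwf"].fractions
    return {
        "identical_group_outputs": bool(identical_files),
        "identical_pipeline_outputs": a == b,
    }
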