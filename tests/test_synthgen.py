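"""The synthetic-image generator's ground-truth contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from wpbq.imgio import read_image
from wpbq.synthgen import (
    PlacementError,
    SyntheticConfig,
    ZONES,
    generate_group,
    generate_image,
)


class TestConfigValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(zone_intensity_fractions=(0.8, 0.3, 0.2))

    def test_negative_geometry_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(pixel_size_um=-0.3)

    def test_coloc_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(coloc_fraction=1.5)


class TestGenerateImage:
    def test_determinism_bit_identical(self):
        a_img, a_gt = generate_image(SyntheticConfig(seed=1))
        b_img, b_gt = generate_image(SyntheticConfig(seed=1))
        for name in a_img.channels:
            assert (a_img[name] == b_img[name]).all()
        pd.testing.assert_frame_equal(a_gt.vesicles, b_gt.vesicles)

    def test_all_perinuclear_condition(self):
        cfg = SyntheticConfig(
            seed=2, vesicle_shape="spot", noise_sd=0.0,
            zone_intensity_fractions=(1.0, 0.0, 0.0),
        )
        img, gt = generate_image(cfg)
        assert (gt.vesicles.distance_um < 2.0).all()
        assert (gt.vesicles.zone == "perinuclear").all()
        np.testing.assert_allclose(gt.zone_fractions["vwf"], (1.0, 0.0, 0.0))

    def test_no_vesicles_only_background(self):
        cfg = SyntheticConfig(
            seed=3, n_vesicles_per_cell=0, noise_sd=0.0,
            zone_intensity_fractions=(0, 0, 0),
        )
        img, gt = generate_image(cfg)
        assert (img["vwf"] == cfg.background_level).all()
        assert len(gt.vesicles) == 0

    def test_fractions_recomputable_from_vesicle_records(self, small_noisefree):
        _, gt = small_noisefree
        assert gt.recompute_zone_fractions("vwf") == gt.zone_fractions["vwf"]

    def test_rendered_mass_matches_truth(self, small_noisefree):
        img, gt = small_noisefree
        cfg = gt.config
        rendered = img["vwf"].astype(float) - cfg.background_level
        total_true = gt.total_signal["vwf"]
        # rounding to integer counts costs < 0.5 per pixel
        assert abs(rendered.sum() - total_true) <= max(0.005 * total_true,
                                                       0.5 * rendered.size)

    def test_noise_changes_pixels_not_ground_truth(self, small_noisefree, small_noisy):
        img0, gt0 = small_noisefree
        img1, gt1 = small_noisy
        pd.testing.assert_frame_equal(gt0.vesicles, gt1.vesicles)
        assert (img0["vwf"] != img1["vwf"]).any()

    def test_vesicles_stay_out_of_nuclei(self, small_noisefree):
        img, gt = small_noisefree
        # nucleus channel is bright on nuclei; vesicle centres must sit in
        # dim nucleus-channel territory
        for _, v in gt.vesicles.iterrows():
            r, c = int(round(v.row)), int(round(v.col))
            assert img["dapi"][r, c] < gt.config.nucleus_intensity / 2

    def test_impossible_layout_raises_placement_error(self):
        with pytest.raises(PlacementError):
            generate_image(SyntheticConfig(image_size_px=(64, 64)))

    def test_min_separation_respected(self):
        cfg = SyntheticConfig(seed=4, n_vesicles_per_cell=20, min_separation_um=2.0)
        _, gt = generate_image(cfg)
        pos = gt.vesicles[["row", "col"]].to_numpy()
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() * cfg.pixel_size_um >= cfg.min_separation_um - 1e-9

    def test_coloc_pairs_sit_on_driver_centres(self):
        cfg = SyntheticConfig(
            seed=5, vesicle_shape="spot", vesicle_channels=("vwf", "rab46"),
            coloc_fraction=0.5, n_vesicles_per_cell=20, min_separation_um=2.0,
        )
        _, gt = generate_image(cfg)
        pairs = gt.coloc_pairs()
        assert len(pairs) == round(0.5 * 2 * 20)
        for _, b in pairs.iterrows():
            a = gt.vesicles.iloc[int(b.pair)]
            assert a.channel == "vwf" and b.channel == "rab46"
            assert np.hypot(a.row - b.row, a.col - b.col) < 1e-9


class TestGenerateGroup:
    def test_layout_and_counts(self, tmp_path):
        cfg = SyntheticConfig(seed=6, n_vesicles_per_cell=5)
        manifest = generate_group(cfg, n_images=5, n_repeats=3, out_dir=tmp_path)
        assert len(manifest) == 15
        tiffs = sorted((tmp_path / "group").rglob("*.tif"))
        assert len(tiffs) == 15
        assert (tmp_path / "group" / "ground_truth.csv").exists()
        img = read_image(tiffs[0], ["dapi", "vwf"])
        assert img["dapi"].shape == tuple(cfg.image_size_px)

    def test_same_seed_identical_files(self, tmp_path):
        cfg = SyntheticConfig(seed=6, n_vesicles_per_cell=5)
        generate_group(cfg, 2, 2, tmp_path / "a", seed=11)
        generate_group(cfg, 2, 2, tmp_path / "b", seed=11)
        for pa in sorted((tmp_path / "a").rglob("*.tif")):
            pb = tmp_path / "b" / pa.relative_to(tmp_path / "a")
            assert pa.read_bytes() == pb.read_bytes()

    def test_zero_repeats_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_group(SyntheticConfig(), 5, 0, tmp_path)


class TestZoneSelfConsistency:
    def test_truth_zones_match_analysis_binning(self, small_noisefree):
        """The generator's zone labels must agree with the 2/5 µm binning
        applied to its own stated distances."""
        _, gt = small_noisefree
        from wpbq.distribution import assign_zone

        for _, v in gt.vesicles.iterrows():
            assert assign_zone(v.distance_um, 1.0) == v.zone
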