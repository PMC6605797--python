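"""Thresholding, mask-processing and distance-map primitives against
independent brute-force oracles and their defining examples."""

import numpy as np
import pytest
from skimage.filters import threshold_isodata as skimage_isodata

from wpbq.segment import (
    DegenerateInputError,
    distance_map,
    label_mask,
    median_filter,
    threshold_bernsen,
    threshold_isodata_default,
    threshold_max_entropy,
    watershed_split,
)

from .oracles import (
    bernsen_naive,
    distance_naive,
    isodata_fixed_points,
    max_entropy_naive,
    median_naive,
)


class TestIsodata:
    def test_two_level_image_splits_at_intermeans(self):
        img = np.array([[10.0] * 8, [200.0] * 8])
        t = threshold_isodata_default(img)
        assert t == 105.0
        assert ((img > t) == (img == 200.0)).all()

    def test_sparse_bright_pixels(self):
        img = np.array([0.0, 0.0, 0.0, 255.0, 255.0])
        t = threshold_isodata_default(img)
        assert ((img > t) == (img == 255.0)).all()
        assert t in isodata_fixed_points(img)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            threshold_isodata_default(np.full((4, 4), 7.0))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_fixed_point_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16)).astype(float)
        t = threshold_isodata_default(img)
        points = isodata_fixed_points(img)
        assert any(np.isclose(t, p, rtol=0, atol=1e-9) for p in points)

    def test_agrees_with_skimage_on_integer_images(self, rng):
        img = np.concatenate(
            [rng.normal(40, 10, 300), rng.normal(180, 20, 200)]
        ).clip(0, 255).astype(int)
        t_ours = threshold_isodata_default(img.astype(float))
        t_ref = skimage_isodata(img)
        # same foreground set up to histogram-bin quantisation
        assert abs((img > t_ours).sum() - (img > t_ref).sum()) <= 2

    def test_shift_equivariance(self, rng):
        img = rng.integers(0, 200, size=(12, 12)).astype(float)
        t = threshold_isodata_default(img)
        t_shift = threshold_isodata_default(img + 50.0)
        assert np.isclose(t_shift, t + 50.0)


class TestMaxEntropy:
    def test_two_value_image(self):
        img = np.array([[10, 10, 200, 200, 10, 10]])
        t = threshold_max_entropy(img)
        assert ((img > t) == (img == 200)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            threshold_max_entropy(np.zeros((3, 3)))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        img = rng.integers(0, 200, size=(16, 16))
        assert threshold_max_entropy(img) == max_entropy_naive(img)

    def test_shift_equivariance(self, rng):
        img = rng.integers(0, 100, size=(10, 10))
        t = threshold_max_entropy(img)
        assert threshold_max_entropy(img + 30) == t + 30


class TestBernsen:
    def test_high_contrast_pixel_above_midgrey_is_foreground(self):
        # window holding min 10 / max 200: midgrey 105, contrast 190
        img = np.full((9, 9), 10.0)
        img[4, 4] = 200.0
        img[4, 5] = 150.0
        mask = threshold_bernsen(img, radius_px=3, contrast_threshold=15)
        assert mask[4, 4] and mask[4, 5]

    def test_flat_region_is_background(self):
        img = np.full((9, 9), 42.0)
        assert not threshold_bernsen(img, radius_px=2, contrast_threshold=15).any()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            threshold_bernsen(np.zeros((8, 8)), radius_px=10)

    @pytest.mark.parametrize("seed,radius", [(s, r) for s in range(10) for r in (2, 4)])
    def test_matches_pixelwise_rule(self, seed, radius):
        rng = np.random.default_rng(200 + seed)
        img = rng.integers(0, 255, size=(16, 16)).astype(float)
        ours = threshold_bernsen(img, radius_px=radius, contrast_threshold=15)
        ref = bernsen_naive(img, radius, 15)
        assert (ours == ref).all()

    def test_additive_offset_invariance(self, rng):
        img = rng.integers(0, 255, size=(20, 20)).astype(float)
        a = threshold_bernsen(img, radius_px=3)
        b = threshold_bernsen(img + 500.0, radius_px=3)
        assert (a == b).all()


class TestMedianFilter:
    def test_isolated_pixel_removed(self):
        img = np.zeros((7, 7), dtype=bool)
        img[3, 3] = True
        assert not median_filter(img, radius_px=1).any()

    def test_constant_image_unchanged(self):
        img = np.full((6, 6), 3.5)
        assert (median_filter(img, radius_px=2) == img).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_windowed_median(self, seed):
        rng = np.random.default_rng(300 + seed)
        img = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        ours = median_filter(img, radius_px=1)
        assert (ours == median_naive(img, 1)).all()


class TestWatershed:
    def test_two_overlapping_discs_split(self):
        yy, xx = np.mgrid[0:80, 0:80]
        mask = (np.hypot(yy - 40, xx - 25) <= 20) | (np.hypot(yy - 40, xx - 55) <= 20)
        labels = watershed_split(mask)
        assert labels.max() == 2
        assert ((labels > 0) == mask).all()

    def test_single_disc_unsplit(self):
        yy, xx = np.mgrid[0:50, 0:50]
        mask = np.hypot(yy - 25, xx - 25) <= 15
        labels = watershed_split(mask)
        assert labels.max() == 1
        assert ((labels > 0) == mask).all()

    def test_empty_mask_empty_labels(self):
        labels = watershed_split(np.zeros((10, 10), dtype=bool))
        assert labels.max() == 0

    def test_never_merges_components(self, rng):
        mask = rng.random((40, 40)) > 0.8
        _, n_cc = label_mask(mask)
        assert watershed_split(mask).max() >= n_cc


class TestDistanceMap:
    def test_single_pixel_euclidean(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        dmap = distance_map(mask)
        assert dmap.values[3, 4] == 5.0
        assert dmap.values[0, 0] == 0.0

    def test_zero_on_mask(self, rng):
        mask = rng.random((20, 20)) > 0.7
        dmap = distance_map(mask)
        assert (dmap.values[mask] == 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            distance_map(np.zeros((5, 5), dtype=bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nearest_pixel_search(self, seed):
        rng = np.random.default_rng(400 + seed)
        mask = rng.random((32, 32)) > 0.95
        if not mask.any():
            mask[0, 0] = True
        dmap = distance_map(mask)
        assert np.allclose(dmap.values, distance_naive(mask))

    def test_lipschitz_property(self, rng):
        mask = rng.random((30, 30)) > 0.9
        mask[4, 4] = True
        d = distance_map(mask).values
        assert np.abs(np.diff(d, axis=0)).max() <= np.sqrt(2) + 1e-9
        assert np.abs(np.diff(d, axis=1)).max() <= np.sqrt(2) + 1e-9

    def test_clipping_at_255(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[0, 0] = True
        dmap = distance_map(mask)
        assert dmap.values.max() > 255.0
        assert dmap.clipped.max() == 255.0
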