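"""pH-front segmentation: color conversion, distance statistics, masks, widths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecllquant import ph_mapping as pm
from ecllquant.ph_mapping import (
    CalibratedImage,
    PhSegmentationSettings,
    RegionOfInterest,
    ColorStats,
)

from conftest import brute_lab


class TestLabConversion:
    def test_white_black_primaries_match_closed_form(self):
        colors = np.array([[[1, 1, 1], [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]], dtype=float)
        np.testing.assert_allclose(pm.rgb_to_lab(colors), brute_lab(colors), atol=1e-6)
        # white maps exactly to the reference white, black to zero
        np.testing.assert_allclose(pm.rgb_to_lab(colors)[0, 0], [100, 0, 0], atol=1e-9)
        np.testing.assert_allclose(pm.rgb_to_lab(colors)[0, 1], [0, 0, 0], atol=1e-9)

    def test_mid_gray_lightness_frozen_oracle(self):
        # L* of sRGB 119/255 computed once with the scalar closed-form oracle
        g = np.full((1, 1, 3), 119 / 255)
        lab = pm.rgb_to_lab(g)[0, 0]
        assert lab[0] == pytest.approx(50.0344388, abs=1e-6)
        assert lab[1] == pytest.approx(0.0, abs=1e-9)

    def test_random_image_matches_scalar_oracle(self, rng):
        rgb = rng.random((8, 8, 3))
        np.testing.assert_allclose(pm.rgb_to_lab(rgb), brute_lab(rgb), atol=1e-9)

    def test_agrees_with_skimage_within_matrix_rounding(self, rng):
        skcolor = pytest.importorskip("skimage.color")
        rgb = rng.random((16, 16, 3))
        assert np.abs(pm.rgb_to_lab(rgb) - skcolor.rgb2lab(rgb)).max() < 5e-3

    def test_round_trip(self, rng):
        rgb = rng.random((8, 8, 3))
        np.testing.assert_allclose(pm.lab_to_rgb(pm.rgb_to_lab(rgb)), rgb, atol=1e-10)

    def test_rejects_single_channel_and_out_of_range(self):
        with pytest.raises(ValueError):
            pm.convert_rgb_to_lab(CalibratedImage(np.zeros((4, 4)), 0.1))
        with pytest.raises(ValueError):
            CalibratedImage(np.full((4, 4, 3), 1.5), 0.1)


class TestRoiColorStats:
    def test_uniform_roi_has_zero_spread(self):
        lab = np.tile(np.array([50.0, 10.0, -5.0]), (6, 6, 1))
        stats = pm.roi_color_stats(lab, RegionOfInterest(0, 6, 0, 6))
        assert stats.mean_distance == 0.0
        assert stats.sd_distance == 0.0
        assert stats.mean_lab == (50.0, 10.0, -5.0)

    def test_checkerboard_of_two_colors(self):
        # two colors separated by distance d: mean at midpoint, all distances d/2
        a, b = np.array([40.0, 0, 0]), np.array([40.0, 6, 8])  # d = 10
        lab = np.empty((4, 4, 3))
        for i in range(4):
            for j in range(4):
                lab[i, j] = a if (i + j) % 2 == 0 else b
        stats = pm.roi_color_stats(lab, RegionOfInterest(0, 4, 0, 4))
        assert stats.mean_distance == pytest.approx(5.0, abs=1e-12)
        assert stats.sd_distance == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(stats.mean_lab, (a + b) / 2, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        lab = rng.normal(50, 20, size=(10, 12, 3))
        roi = RegionOfInterest(2, 9, 3, 11)
        stats = pm.roi_color_stats(lab, roi)
        px = [lab[i, j] for i in range(2, 9) for j in range(3, 11)]
        mean = sum(px) / len(px)
        dists = [float(np.sqrt(((p - mean) ** 2).sum())) for p in px]
        md = sum(dists) / len(dists)
        sd = (sum((d - md) ** 2 for d in dists) / len(dists)) ** 0.5
        np.testing.assert_allclose(stats.mean_lab, mean, atol=1e-9)
        assert stats.mean_distance == pytest.approx(md, abs=1e-9)
        assert stats.sd_distance == pytest.approx(sd, abs=1e-9)

    def test_roi_outside_image_rejected(self):
        lab = np.zeros((5, 5, 3))
        with pytest.raises(ValueError):
            pm.roi_color_stats(lab, RegionOfInterest(0, 6, 0, 5))
        with pytest.raises(ValueError):
            RegionOfInterest(3, 3, 0, 5)  # empty


class TestDistanceMap:
    def test_uniform_equals_reference_is_zero(self):
        lab = np.tile(np.array([60.0, 1.0, 2.0]), (5, 5, 1))
        assert pm.distance_map(lab, (60.0, 1.0, 2.0)).max() == 0.0

    def test_three_four_five(self):
        lab = np.zeros((2, 2, 3))
        lab[0, 1] = [3.0, 4.0, 0.0]
        dmap = pm.distance_map(lab, (0.0, 0.0, 0.0))
        assert dmap[0, 1] == pytest.approx(5.0)
        assert dmap[0, 0] == 0.0

    def test_matches_per_pixel_loop(self, rng):
        lab = rng.normal(0, 30, size=(7, 9, 3))
        ref = (12.0, -4.0, 7.0)
        dmap = pm.distance_map(lab, ref)
        for i in range(7):
            for j in range(9):
                expect = float(np.sqrt(((lab[i, j] - np.array(ref)) ** 2).sum()))
                assert dmap[i, j] == pytest.approx(expect, abs=1e-9)


class TestSegmentByDistance:
    def test_image_at_mean_color_fully_retained(self):
        stats = ColorStats((50, 0, 0), mean_distance=0.0, sd_distance=0.0, n_pixels=9)
        dmap = np.zeros((4, 4))
        assert pm.segment_by_distance(dmap, stats).all()

    def test_far_outlier_excluded(self):
        stats = ColorStats((50, 0, 0), mean_distance=2.0, sd_distance=1.0, n_pixels=9)
        dmap = np.full((3, 3), 2.0)
        dmap[1, 1] = 2.0 + 10.0  # mean + 10 SD
        mask = pm.segment_by_distance(dmap, stats, sd_multiplier=1.0)
        assert not mask[1, 1] and mask.sum() == 8

    def test_negative_multiplier_rejected(self):
        stats = ColorStats((0, 0, 0), 0.0, 0.0, 1)
        with pytest.raises(ValueError):
            pm.segment_by_distance(np.zeros((2, 2)), stats, sd_multiplier=-1)


class TestCleanMask:
    def test_fills_interior_hole(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        mask[4, 4] = False
        cleaned = pm.clean_mask(mask, min_component_px=1)
        assert cleaned[4, 4]

    def test_drops_isolated_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        assert not pm.clean_mask(mask, min_component_px=10).any()

    def test_matches_flood_fill_labeling_oracle(self, rng):
        from scipy import ndimage as ndi

        mask = rng.random((20, 20)) > 0.55
        cleaned = pm.clean_mask(mask, min_component_px=5)
        # oracle: fill holes by flood fill from the border, drop components < 5
        padded = np.pad(~mask, 1, constant_values=True)
        lab_bg, _ = ndi.label(padded)  # 4-connectivity background
        border_label = lab_bg[0, 0]
        filled = ~((lab_bg == border_label)[1:-1, 1:-1])
        lab_fg, n = ndi.label(filled, structure=np.ones((3, 3)))
        keep = np.zeros_like(filled)
        for lbl in range(1, n + 1):
            comp = lab_fg == lbl
            if comp.sum() >= 5:
                keep |= comp
        np.testing.assert_array_equal(cleaned, keep)

    def test_idempotent_and_never_gains_components(self, rng):
        from scipy import ndimage as ndi

        mask = rng.random((30, 30)) > 0.6
        once = pm.clean_mask(mask, min_component_px=4)
        np.testing.assert_array_equal(once, pm.clean_mask(once, min_component_px=4))
        s8 = np.ones((3, 3))
        assert ndi.label(once, structure=s8)[1] <= ndi.label(mask, structure=s8)[1]


class TestMeanRowWidth:
    def test_solid_rectangle(self):
        mask = np.zeros((50, 60), dtype=bool)
        mask[10:40, 5:35] = True  # 30 px wide
        assert pm.mean_row_width(mask, 0.1) == pytest.approx(3.0)

    def test_mean_over_occupied_rows_only(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[2, :10] = True
        mask[7, :20] = True
        assert pm.mean_row_width(mask, 1.0) == pytest.approx(15.0)

    def test_empty_mask_is_zero(self):
        assert pm.mean_row_width(np.zeros((5, 5), dtype=bool), 0.1) == 0.0

    def test_matches_row_loop_oracle(self, rng):
        mask = rng.random((15, 25)) > 0.5
        widths = [row.sum() for row in mask if row.sum() > 0]
        expect = 0.07 * sum(widths) / len(widths)
        assert pm.mean_row_width(mask, 0.07) == pytest.approx(expect, abs=1e-12)

    def test_translation_invariant(self, rng):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 5:20] = rng.random((10, 15)) > 0.4
        shifted = np.roll(np.roll(mask, 7, axis=0), 9, axis=1)
        assert pm.mean_row_width(mask, 0.1) == pm.mean_row_width(shifted, 0.1)


class TestCalibrateScale:
    @pytest.mark.parametrize("px,mm,expect", [(100, 10, 0.1), (250, 10, 0.04)])
    def test_known_rulers(self, px, mm, expect):
        assert pm.calibrate_scale(px, mm) == pytest.approx(expect)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pm.calibrate_scale(0, 10)
        with pytest.raises(ValueError):
            pm.calibrate_scale(100, -1)


class TestMeasurePhWidths:
    def _banded_image(self, scale=0.05, aw=2.0, cw=3.0, noise=0.0, seed=0, size=(120, 400)):
        from ecllquant import synthetic

        truth = synthetic.PhMapTruth(anode_width_mm=aw, cathode_width_mm=cw,
                                     noise_sd=noise, scale_mm_per_px=scale,
                                     electrode_spacing_mm=max(3.0, (aw + cw) / 2 + 1),
                                     seed=seed)
        img, truth = synthetic.make_ph_image(truth, size)
        ra, rc = synthetic.default_ph_rois(truth, size)
        return img, RegionOfInterest(*ra), RegionOfInterest(*rc), truth

    def test_noiseless_band_recovered_to_boundary_pixel(self):
        img, ra, rc, truth = self._banded_image()
        res = pm.measure_ph_widths(img, ra, rc)
        assert res.anode_width_mm == pytest.approx(2.0, abs=2 * 0.05)
        assert res.cathode_width_mm == pytest.approx(3.0, abs=2 * 0.05)

    def test_noisy_band_within_tolerance(self):
        img, ra, rc, truth = self._banded_image(noise=2.0, seed=3)
        res = pm.measure_ph_widths(img, ra, rc)
        assert res.anode_width_mm == pytest.approx(2.0, abs=0.2)
        assert res.cathode_width_mm == pytest.approx(3.0, abs=0.2)

    def test_resolution_doubling_with_halved_scale_invariant(self):
        img, ra, rc, truth = self._banded_image()
        res1 = pm.measure_ph_widths(img, ra, rc)
        big = np.repeat(np.repeat(img.pixels, 2, axis=0), 2, axis=1)
        img2 = CalibratedImage(big, img.scale_mm_per_px / 2)
        res2 = pm.measure_ph_widths(
            img2,
            RegionOfInterest(2 * ra.row_start, 2 * ra.row_end, 2 * ra.col_start, 2 * ra.col_end),
            RegionOfInterest(2 * rc.row_start, 2 * rc.row_end, 2 * rc.col_start, 2 * rc.col_end),
        )
        assert res2.anode_width_mm == pytest.approx(res1.anode_width_mm, abs=img.scale_mm_per_px)
        assert res2.cathode_width_mm == pytest.approx(res1.cathode_width_mm, abs=img.scale_mm_per_px)

    def test_overlapping_rois_rejected(self):
        img, ra, rc, _ = self._banded_image()
        with pytest.raises(ValueError):
            pm.measure_ph_widths(img, ra, ra)

    def test_deterministic(self):
        img, ra, rc, _ = self._banded_image(noise=2.0, seed=5)
        r1 = pm.measure_ph_widths(img, ra, rc)
        r2 = pm.measure_ph_widths(img, ra, rc)
        assert r1.anode_width_mm == r2.anode_width_mm
        np.testing.assert_array_equal(r1.cathode_mask.mask, r2.cathode_mask.mask)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_clean_mask_idempotence_property(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((16, 16)) > 0.5
    once = pm.clean_mask(mask, min_component_px=3)
    np.testing.assert_array_equal(once, pm.clean_mask(once, min_component_px=3))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_distance_map_zero_iff_equal_property(seed):
    rng = np.random.default_rng(seed)
    lab = rng.normal(0, 10, size=(6, 6, 3))
    ref = tuple(lab[2, 3])
    dmap = pm.distance_map(lab, ref)
    assert dmap[2, 3] == pytest.approx(0.0, abs=1e-12)
    assert (dmap >= 0).all()
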