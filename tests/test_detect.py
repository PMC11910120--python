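"""Front detection pipeline: saturation, Otsu, profiles, localization."""

import numpy as np
import pytest
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu as skimage_otsu

from idafront.chemistry import BROMOTHYMOL_BLUE
from idafront.detect import (
    CalibrationModel,
    DetectionConfig,
    NoInterfaceError,
    VialROI,
    binarize,
    detect_interface,
    estimate_homography,
    mm_to_px,
    otsu_threshold,
    px_to_mm,
    rectify,
    row_profile,
    saturation_image,
    track_series,
)
from idafront.synth import RenderConfig, render_frame, render_multivial, render_series


def brute_force_otsu(values: np.ndarray) -> float:
    """Independent exhaustive between-class variance maximization."""
    vals = np.asarray(values, float).ravel()
    best_cut, best_sb = None, -1.0
    uniq = np.unique(vals)
    for cut in (uniq[:-1] + uniq[1:]) / 2:
        lo, hi = vals[vals <= cut], vals[vals > cut]
        w0 = len(lo) / len(vals)
        sb = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if sb > best_sb:
            best_sb, best_cut = sb, cut
    return best_cut


class TestSaturation:
    def test_gray_pixel_has_zero_saturation(self):
        assert saturation_image(np.full((1, 1, 3), 0.3))[0, 0] == 0.0

    def test_pure_blue_is_fully_saturated(self):
        assert saturation_image(np.array([[[0.0, 0.0, 1.0]]]))[0, 0] == 1.0

    def test_worked_example(self):
        assert saturation_image(np.array([[[0.8, 0.4, 0.4]]]))[0, 0] == pytest.approx(0.5)

    def test_black_pixel_defined_as_zero(self):
        assert saturation_image(np.zeros((1, 1, 3)))[0, 0] == 0.0

    def test_agrees_with_skimage_hsv(self):
        img = np.random.default_rng(3).random((16, 16, 3))
        np.testing.assert_allclose(saturation_image(img), rgb2hsv(img)[..., 1], atol=1e-12)


class TestOtsu:
    def test_bimodal_classes_exactly_recovered(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((20, 10)) < 0.5, 0.1, 0.9)
        binary = binarize(img, DetectionConfig())
        np.testing.assert_array_equal(binary, img > 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_maximization(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate(
            [rng.normal(0.25, 0.04, 120), rng.normal(0.75, 0.04, 80)]
        ).clip(0, 1)
        ours = otsu_threshold(vals)
        ref = brute_force_otsu(vals)
        lo, hi = vals[vals <= ours], vals[vals > ours]
        lo2, hi2 = vals[vals <= ref], vals[vals > ref]
        assert len(lo) == len(lo2) and len(hi) == len(hi2)

    def test_partitions_like_skimage_on_noisy_image(self):
        # Thresholds may land anywhere in the sparsely populated inter-mode
        # gap; what matters is that the class partitions agree.
        rng = np.random.default_rng(7)
        img = np.concatenate(
            [rng.normal(0.3, 0.05, 500), rng.normal(0.8, 0.05, 500)]
        ).clip(0, 1)
        ours = otsu_threshold(img)
        ref = skimage_otsu(img, nbins=256)
        assert np.mean((img > ours) == (img > ref)) > 0.99

    def test_fixed_threshold_split(self):
        img = np.where(np.arange(100).reshape(10, 10) < 50, 0.4, 0.6)
        cfg = DetectionConfig(threshold_method="fixed", fixed_threshold=0.5)
        np.testing.assert_array_equal(binarize(img, cfg), img > 0.5)

    def test_constant_image_raises(self):
        with pytest.raises(NoInterfaceError):
            binarize(np.full((5, 5), 0.5), DetectionConfig())


class TestRectify:
    def test_identity_is_noop(self):
        img = np.random.default_rng(0).random((20, 20, 3))
        np.testing.assert_array_equal(rectify(img, CalibrationModel()), img)

    def test_pure_translation_shifts_columns(self):
        img = np.zeros((20, 30, 3))
        img[:, 10] = 1.0
        h = np.eye(3)
        h[0, 2] = 5.0  # maps x -> x + 5
        out = rectify(img, CalibrationModel(homography=h))
        assert out[10, 15, 0] == pytest.approx(1.0)
        assert out[10, 10, 0] == pytest.approx(0.0)

    def test_warp_roundtrip_small_error(self):
        yy, xx = np.mgrid[0:60, 0:60]
        img = (0.5 + 0.4 * np.sin(xx / 9.0) * np.cos(yy / 7.0))[..., None].repeat(3, -1)
        h = np.array([[1.01, 0.02, -1.0], [-0.01, 0.99, 2.0], [1e-5, -1e-5, 1.0]])
        fwd = rectify(img, CalibrationModel(homography=h))
        back = rectify(fwd, CalibrationModel(homography=np.linalg.inv(h)))
        interior = np.s_[10:50, 10:50]
        assert np.max(np.abs(back[interior] - img[interior])) < 2 / 255

    def test_singular_homography_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            CalibrationModel(homography=np.zeros((3, 3)))

    def test_estimate_homography_recovers_translation(self):
        src = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        dst = src + [3, 0]
        h = estimate_homography(src, dst)
        np.testing.assert_allclose(h / h[2, 2], [[1, 0, 3], [0, 1, 0], [0, 0, 1]], atol=1e-9)


class TestRowProfile:
    def test_all_foreground_gives_ones(self, roi):
        binary = np.ones((roi.height, roi.col_end - roi.col_start), bool)
        np.testing.assert_array_equal(row_profile(binary, roi), np.ones(roi.height))

    def test_window_one_is_identity(self, roi):
        rng = np.random.default_rng(0)
        binary = rng.random((roi.height, roi.col_end - roi.col_start)) > 0.5
        cfg = DetectionConfig(smooth_window_rows=1)
        np.testing.assert_array_equal(row_profile(binary, roi, cfg), binary.mean(axis=1))

    def test_step_smoothed_to_window_wide_ramp(self, roi):
        binary = np.zeros((roi.height, roi.col_end - roi.col_start), bool)
        binary[: roi.height // 2] = True
        p = row_profile(binary, roi, DetectionConfig(smooth_window_rows=5))
        ramp = np.flatnonzero((p > 0) & (p < 1))
        assert len(ramp) == 4  # 5-row window -> 4 intermediate values

    def test_empty_roi_rejected(self, roi):
        with pytest.raises(ValueError, match="empty ROI"):
            row_profile(np.ones((2, 2), bool), roi)


class TestDetectInterface:
    def make_roi(self, n=100):
        return VialROI(0, 10, 0, n, 0)

    def test_unit_step_interpolates_to_midpoint(self):
        roi = self.make_roi()
        p = np.ones(100)
        p[50:] = 0.0  # step between rows 49 and 50
        hit = detect_interface(p, roi, DetectionConfig(smooth_window_rows=1))
        assert hit.row == pytest.approx(49.5)

    def test_linear_interpolation_between_brackets(self):
        roi = self.make_roi()
        p = np.ones(100)
        p[49] = 0.8
        p[50:] = 0.2
        hit = detect_interface(p, roi, DetectionConfig(smooth_window_rows=1))
        assert hit.row == pytest.approx(49.5)  # (0.8-0.5)/(0.8-0.2)

    def test_profile_above_level_everywhere_flags_no_interface(self):
        roi = self.make_roi()
        p = np.linspace(1.0, 0.7, 100)
        hit = detect_interface(p, roi, DetectionConfig(smooth_window_rows=1))
        assert hit.flag == "no_interface" and hit.row is None

    def test_low_contrast_profile_rejected(self):
        roi = self.make_roi()
        p = 0.5 + 0.05 * np.sin(np.arange(100))
        hit = detect_interface(p, roi, DetectionConfig(smooth_window_rows=1))
        assert hit.flag == "no_interface"

    def test_multiple_crossings_keep_topmost(self):
        roi = self.make_roi()
        p = np.ones(100)
        p[30:40] = 0.0
        p[40:] = 1.0
        p[70:] = 0.0
        hit = detect_interface(p, roi, DetectionConfig(smooth_window_rows=1))
        assert hit.row == pytest.approx(29.5)
        assert hit.n_crossings == 2


class TestEndToEndDetection:
    def test_noise_free_oracle_within_half_pixel(self, geometry, roi, clean_render, detection):
        cal = CalibrationModel(mm_per_px=geometry.mm_per_px)
        for depth in np.arange(0.6, 4.71, 0.25):
            frame = render_frame(depth, geometry, BROMOTHYMOL_BLUE, clean_render)
            sat = saturation_image(frame)
            crop = sat[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
            hit = detect_interface(row_profile(binarize(crop), roi, detection), roi, detection)
            assert hit.flag == "ok"
            err_px = (hit.row - geometry.gel_top_row) - depth / geometry.mm_per_px
            assert abs(err_px) < 0.5, f"depth {depth} mm: error {err_px} px"

    def test_translation_equivariance(self, geometry, clean_render, detection):
        frame = render_frame(2.5, geometry, BROMOTHYMOL_BLUE, clean_render)
        k = 7
        shifted = np.roll(frame, k, axis=0)
        for img, offset in [(frame, 0), (shifted, k)]:
            roi_k = VialROI(
                0,
                geometry.width_px,
                geometry.gel_top_row + offset,
                geometry.gel_bottom_row + offset,
                geometry.gel_top_row + offset,
            )
            sat = saturation_image(img)
            crop = sat[roi_k.row_start : roi_k.row_end, roi_k.col_start : roi_k.col_end]
            hit = detect_interface(row_profile(binarize(crop), roi_k, detection), roi_k, detection)
            if offset == 0:
                base = hit.row
            else:
                assert hit.row == pytest.approx(base + k, abs=1e-9)

    def test_brightness_scaling_invariance(self, geometry, roi, clean_render, detection):
        frame = render_frame(3.0, geometry, BROMOTHYMOL_BLUE, clean_render)
        rows = []
        for scale in (1.0, 0.7, 0.5):
            sat = saturation_image(frame * scale)
            crop = sat[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
            hit = detect_interface(row_profile(binarize(crop), roi, detection), roi, detection)
            rows.append(hit.row)
        assert rows[0] == pytest.approx(rows[1], abs=1e-9)
        assert rows[0] == pytest.approx(rows[2], abs=1e-9)

    def test_track_recovers_truth_on_clean_series(
        self, geometry, roi, protocol_times, clean_render, calibration
    ):
        series = render_series(protocol_times, 11.55e-9, geometry, BROMOTHYMOL_BLUE, clean_render)
        (track,) = track_series(series, [roi], calibration)
        for i, (flag, tflag) in enumerate(zip(track.flags, series.truth_flags)):
            if flag != "ok" or tflag != "ok" or series.times_s[i] == 0:
                continue
            assert abs(track.position_mm[i] - series.truth_depth_mm[i]) < 0.5 * geometry.mm_per_px

    def test_identical_frames_give_zero_displacement(
        self, geometry, roi, clean_render, calibration
    ):
        from idafront.synth import FrameSeries

        frame = render_frame(2.0, geometry, BROMOTHYMOL_BLUE, clean_render)
        times = np.array([0.0, 300.0, 600.0])
        series = FrameSeries(
            [frame.copy() for _ in times], times, np.full(3, 2.0), np.array(["ok"] * 3)
        )
        (track,) = track_series(series, [roi], calibration)
        ok = [i for i, f in enumerate(track.flags) if f == "ok"]
        assert len(ok) == 3
        np.testing.assert_allclose(track.position_mm[ok], 0.0, atol=1e-9)

    def test_noisy_vials_agree_within_two_pixels(self, geometry, protocol_times, calibration):
        cfg = RenderConfig(noise_sd=0.02, seed=11)
        series, rois = render_multivial(
            [(11.55e-9, geometry)] * 10, protocol_times, BROMOTHYMOL_BLUE, cfg
        )
        tracks = track_series(series, [VialROI(*r) for r in rois], calibration)
        pos = np.stack([t.position_px for t in tracks])  # (vial, time)
        for j in range(1, len(protocol_times)):
            col = pos[:, j]
            col = col[np.isfinite(col)]
            if len(col) >= 5:
                assert col.std(ddof=1) < 2.0


class TestConversion:
    def test_published_conversion_factor(self):
        cal = CalibrationModel(mm_per_px=0.0681)
        assert px_to_mm(100.0, cal) == pytest.approx(6.81)

    def test_zero_maps_to_zero(self, calibration):
        assert px_to_mm(0.0, calibration) == 0.0

    def test_inverse_consistency(self, calibration):
        assert mm_to_px(px_to_mm(37.2, calibration), calibration) == pytest.approx(37.2)
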