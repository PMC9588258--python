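"""EPID strip-test analysis: correction, ROIs, deviations, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drgsqa import (
    BaselineError,
    BaselineRecord,
    EpidImage,
    ImageError,
    LayoutError,
    RoiSpec,
    StripLayout,
    compare_to_baseline,
    corrected_image,
    locate_rois,
    make_epid_pair,
    read_rtimage,
    segment_deviations,
    update_baseline,
    write_rtimage,
)
from conftest import small_epid_config

# Published per-ROI means and baselines of one routine DRGS session
SESSION_MEASURED = [1.01, 1.001, 1.0, 0.996, 0.994, 0.998, 1.0]
SESSION_BASELINE = [1.012, 1.004, 1.002, 0.992, 0.995, 0.998, 0.997]
SESSION_DIFFS_1DP = [-0.2, -0.3, -0.2, 0.4, -0.1, 0.0, 0.3]


def strip_of_means(means):
    """A 1 x n corrected image with one single-pixel ROI per segment."""
    arr = np.asarray(means, dtype=float)[None, :]
    rois = [RoiSpec(i + 1, 0, 1, i, i + 1) for i in range(len(means))]
    return arr, rois


class TestCorrectedImage:
    def test_identical_images_give_all_ones(self):
        img = EpidImage(np.full((8, 8), 42.0), (1.0, 1.0), kind="OPEN")
        strip = EpidImage(np.full((8, 8), 42.0), (1.0, 1.0), kind="STRIP")
        assert np.allclose(corrected_image(strip, img), 1.0)

    def test_half_intensity_strip(self):
        open_ = EpidImage(np.full((4, 4), 100.0), (1.0, 1.0), kind="OPEN")
        strip = EpidImage(np.full((4, 4), 50.0), (1.0, 1.0), kind="STRIP")
        assert np.allclose(corrected_image(strip, open_), 0.5)

    def test_planted_factors_recovered_exactly_without_noise(self, small_config):
        factors = (1.0, 0.97, 1.02, 1.0, 1.05, 1.0, 0.99)
        strip, open_, truth = make_epid_pair(small_epid_config(roi_factors=factors))
        corrected = corrected_image(strip, open_)
        for roi, f in zip(locate_rois(truth["layout"], strip), factors):
            block = corrected[roi.slices]
            assert np.max(np.abs(block - f)) < 1e-12

    def test_dimension_mismatch_is_an_error(self):
        a = EpidImage(np.ones((4, 4)), (1.0, 1.0))
        b = EpidImage(np.ones((4, 5)), (1.0, 1.0))
        with pytest.raises(ImageError, match="shape"):
            corrected_image(a, b)

    def test_low_open_field_pixels_are_masked(self):
        open_pixels = np.full((4, 4), 100.0)
        open_pixels[0, 0] = 0.1  # below 5% of median
        open_ = EpidImage(open_pixels, (1.0, 1.0), kind="OPEN")
        strip = EpidImage(np.full((4, 4), 50.0), (1.0, 1.0), kind="STRIP")
        corrected = corrected_image(strip, open_)
        assert corrected.mask[0, 0] and not corrected.mask[1:].any()


class TestLocateRois:
    def test_default_margin_keeps_central_half_of_each_strip(self):
        layout = StripLayout(rows=(100, 600), strips=[(200 + 100 * i, 240 + 100 * i) for i in range(7)])
        image = EpidImage(np.ones((768, 1024)), (0.336, 0.336))
        rois = locate_rois(layout, image, margin_fraction=0.25)
        assert [(r.col_start, r.col_stop) for r in rois] == [
            (210 + 100 * i, 230 + 100 * i) for i in range(7)
        ]
        assert all(r.row_start == 110 and r.row_stop == 590 for r in rois)

    def test_zero_margin_returns_full_apertures(self):
        layout = StripLayout(rows=(10, 50), strips=[(0, 10), (20, 30)])
        image = EpidImage(np.ones((60, 40)), (1.0, 1.0))
        rois = locate_rois(layout, image, margin_fraction=0.0)
        assert [(r.col_start, r.col_stop) for r in rois] == [(0, 10), (20, 30)]

    def test_half_margin_degenerates(self):
        layout = StripLayout(rows=(10, 50), strips=[(0, 10), (20, 30)])
        image = EpidImage(np.ones((60, 40)), (1.0, 1.0))
        with pytest.raises(LayoutError, match="degenerate"):
            locate_rois(layout, image, margin_fraction=0.5)

    def test_strip_outside_image_rejected(self):
        layout = StripLayout(rows=(0, 10), strips=[(30, 50)])
        image = EpidImage(np.ones((10, 40)), (1.0, 1.0))
        with pytest.raises(LayoutError, match="outside"):
            locate_rois(layout, image, margin_fraction=0.0)


class TestSegmentDeviations:
    def test_equal_means_give_zero_deviations(self):
        arr, rois = strip_of_means([1.0] * 7)
        assert [d.deviation_pct for d in segment_deviations(arr, rois)] == pytest.approx([0.0] * 7)

    def test_one_hot_segment_closed_form(self):
        arr, rois = strip_of_means([1.07] + [1.0] * 6)
        devs = [d.deviation_pct for d in segment_deviations(arr, rois)]
        assert devs[0] == pytest.approx((1.07 / 1.01 - 1) * 100, abs=5e-3)  # +5.94
        assert devs[1:] == pytest.approx([(1.0 / 1.01 - 1) * 100] * 6, abs=5e-3)  # -0.99

    def test_session_means_deviation_of_first_roi(self):
        arr, rois = strip_of_means(SESSION_MEASURED)
        devs = segment_deviations(arr, rois)
        assert round(devs[0].deviation_pct, 2) == 1.01

    def test_zero_mean_invariant(self):
        rng = np.random.default_rng(7)
        arr, rois = strip_of_means(rng.uniform(0.9, 1.1, size=7))
        devs = segment_deviations(arr, rois)
        assert abs(np.mean([d.deviation_pct for d in devs])) < 1e-9

    @given(st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance_of_deviations(self, scale):
        means = [1.01, 0.98, 1.0, 1.03, 0.99, 1.0, 1.0]
        base, rois = strip_of_means(means)
        scaled, _ = strip_of_means([scale * m for m in means])
        got = [d.deviation_pct for d in segment_deviations(scaled, rois)]
        want = [d.deviation_pct for d in segment_deviations(base, rois)]
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("delta", [0.01, 0.03, 0.07])
    def test_perturbation_recovery_matches_closed_form(self, delta):
        """One of 7 equal strips boosted by (1+d) deviates by ((1+d)/(1+d/7)-1)x100."""
        factors = [1.0] * 7
        factors[3] = 1.0 + delta
        strip, open_, truth = make_epid_pair(small_epid_config(roi_factors=tuple(factors)))
        rois = locate_rois(truth["layout"], strip)
        devs = segment_deviations(corrected_image(strip, open_), rois)
        expected = ((1 + delta) / (1 + delta / 7) - 1) * 100
        assert devs[3].deviation_pct == pytest.approx(expected, rel=1e-4)

    def test_fully_masked_roi_is_an_error(self):
        arr = np.ma.MaskedArray(np.ones((2, 4)), mask=np.zeros((2, 4), bool))
        arr.mask[:, 2:] = True
        rois = [RoiSpec(1, 0, 2, 0, 2), RoiSpec(2, 0, 2, 2, 4)]
        with pytest.raises(ImageError, match="ROI 2"):
            segment_deviations(arr, rois)


class TestBaselineComparison:
    def test_session_reproduces_published_differences(self):
        baseline = BaselineRecord(machine_id="TB1", baseline_means=SESSION_BASELINE)
        report = compare_to_baseline(SESSION_MEASURED, baseline, tolerance_pct=3.0)
        assert report.differences_rounded == SESSION_DIFFS_1DP
        assert round(report.max_abs_difference_pct, 1) == 0.4
        assert report.passed

    def test_identical_measurement_passes_with_zero_difference(self):
        baseline = BaselineRecord(machine_id="TB1", baseline_means=[1.0] * 7)
        report = compare_to_baseline([1.0] * 7, baseline)
        assert report.differences_rounded == [0.0] * 7
        assert report.max_abs_difference_pct == 0.0
        assert report.passed

    def test_four_percent_shift_fails_three_percent_tolerance(self):
        baseline = BaselineRecord(machine_id="TB1", baseline_means=[1.0] * 7)
        measured = [1.0] * 7
        measured[2] = 1.04
        report = compare_to_baseline(measured, baseline, tolerance_pct=3.0)
        assert not report.rows[2].passed
        assert not report.passed

    def test_roi_count_mismatch_is_an_error(self):
        baseline = BaselineRecord(machine_id="TB1", baseline_means=[1.0] * 7)
        with pytest.raises(BaselineError, match="ROI"):
            compare_to_baseline([1.0] * 6, baseline)

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(BaselineError):
            BaselineRecord(machine_id="TB1", baseline_means=[1.0, 0.0, 1.0])

    def test_baseline_json_round_trip(self, tmp_path):
        record = BaselineRecord("TB1", SESSION_BASELINE, date_range="2020-01..2022-03", n_sessions=27)
        path = record.to_json(tmp_path / "baseline.json")
        back = BaselineRecord.from_json(path)
        assert back == record


class TestUpdateBaseline:
    def test_single_session_is_the_baseline(self):
        record = update_baseline([SESSION_MEASURED])
        assert record.baseline_means == pytest.approx(SESSION_MEASURED)
        assert record.n_sessions == 1

    def test_two_sessions_average(self):
        record = update_baseline([[1.00, 1.0], [1.02, 1.0]])
        assert record.baseline_means[0] == pytest.approx(1.01)

    def test_27_sessions_recover_truth_within_standard_error(self):
        rng = np.random.default_rng(42)
        truth, sigma, n = 1.005, 0.002, 27
        history = rng.normal(truth, sigma, size=(n, 7))
        record = update_baseline(history.tolist())
        bound = 3 * sigma / np.sqrt(n)
        assert all(abs(v - truth) < bound for v in record.baseline_means)

    def test_ragged_sessions_rejected(self):
        with pytest.raises(BaselineError, match="inconsistent"):
            update_baseline([[1.0, 1.0], [1.0]])


class TestRtImageIO:
    def test_write_read_preserves_signal_and_spacing(self, tmp_path, noiseless_pair):
        strip, _, _ = noiseless_pair
        path = write_rtimage(strip, tmp_path / "strip.dcm")
        back = read_rtimage(path)
        assert back.kind == "STRIP"
        assert back.pixel_spacing == strip.pixel_spacing
        # 16-bit storage: relative error bounded by one stored level
        assert np.max(np.abs(back.pixels - strip.pixels)) < strip.pixels.max() / 65535.0
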