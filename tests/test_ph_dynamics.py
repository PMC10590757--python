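"""Calibration, peak detection, per-cycle pH metrics and event timing."""

import math
from dataclasses import replace

import numpy as np
import pytest

import vacuoscope as v
from vacuoscope.ph_dynamics import CalibrationError, ConversionError, Peak


class TestCalibrationFit:
    def test_exact_linear_data_recovered(self):
        r = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        series = v.CalibrationSeries(ph=4.0 + 2.0 * r, ratio=r)
        fit = v.fit_calibration(series, mode="linear")
        assert fit.intercept == pytest.approx(4.0) and fit.slope == pytest.approx(2.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_least_squares_hand_example(self):
        # normal equations for (R, pH) = (1,5), (2,6), (3,7.3): b=1.15, a=3.8
        series = v.CalibrationSeries(
            ph=[5.0, 6.0, 7.3, 5.0, 6.0, 7.3], ratio=[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        )
        fit = v.fit_calibration(series, mode="linear")
        assert fit.slope == pytest.approx(1.15)
        assert fit.intercept == pytest.approx(3.8)

    def test_three_points_rejected(self):
        with pytest.raises(CalibrationError):
            v.fit_calibration(v.CalibrationSeries(ph=[5.0, 6.0, 7.0], ratio=[1.0, 2.0, 3.0]))

    def test_decreasing_trend_rejected(self):
        series = v.CalibrationSeries(ph=[5.0, 5.5, 6.0, 6.5, 7.0], ratio=[5, 4, 3, 2, 1])
        with pytest.raises(CalibrationError):
            v.fit_calibration(series)

    def test_sigmoid_fit_recovers_titration_parameters(self):
        series = v.make_calibration_series((v.BCECF, v.MCHERRY), noise_sd=0.0)
        fit = v.fit_calibration(series, mode="sigmoid")
        assert fit.params["pka"] == pytest.approx(6.98, abs=1e-6)
        assert fit.params["hill"] == pytest.approx(1.0, abs=1e-6)


class TestRatioToPh:
    def test_series_midpoint_maps_back(self):
        r = np.array([0.5, 1.0, 1.5, 2.0])
        fit = v.fit_calibration(v.CalibrationSeries(ph=4.0 + 2.0 * r, ratio=r), mode="linear")
        ph, flags = v.ratio_to_ph(fit, np.array([1.25]))
        assert ph[0] == pytest.approx(6.5) and not flags[0]

    def test_noise_free_round_trip_within_002(self):
        series = v.make_calibration_series((v.BCECF, v.MCHERRY), noise_sd=0.0)
        fit = v.fit_calibration(series, mode="sigmoid")
        truth = np.linspace(5.1, 7.4, 200)
        est, flags = v.ratio_to_ph(fit, v.BCECF.intensity(truth))
        assert not flags.any()
        assert np.max(np.abs(est - truth)) < 0.02

    def test_rmse_scales_with_noise(self):
        truth = np.full(4000, 6.0)
        rng = np.random.default_rng(0)
        rmses = []
        for noise in (0.005, 0.02):
            series = v.make_calibration_series((v.BCECF, v.MCHERRY), noise_sd=0.0)
            fit = v.fit_calibration(series, mode="sigmoid")
            ratio = v.BCECF.intensity(truth + rng.normal(0, noise, truth.size))
            est, _ = v.ratio_to_ph(fit, ratio)
            rmses.append(np.sqrt(np.mean((est - truth) ** 2)))
        assert rmses[1] / rmses[0] == pytest.approx(4.0, rel=0.25)

    def test_extrapolation_is_flagged(self, bcecf_calibration_fit):
        ratio = v.BCECF.intensity(np.array([4.0, 6.0]))  # 1 pH unit below range
        ph, flags = v.ratio_to_ph(bcecf_calibration_fit, ratio)
        assert flags[0] and not flags[1]

    def test_all_out_of_range_raises(self):
        r = np.array([0.5, 1.0, 1.5, 2.0])
        fit = v.fit_calibration(v.CalibrationSeries(ph=4.0 + 2.0 * r, ratio=r), mode="linear")
        with pytest.raises(ConversionError):
            v.ratio_to_ph(fit, np.array([50.0, 60.0]))


class TestDetectPeaks:
    def test_constant_trace_has_no_peaks(self):
        t = np.arange(100) * 2.0
        assert v.detect_peaks(np.full(100, 6.0), t) == []

    def test_subthreshold_bump_ignored(self):
        t = np.arange(200) * 1.0
        trace = (
            1.0 * np.exp(-0.5 * ((t - 60) / 4.0) ** 2)
            + 0.1 * np.exp(-0.5 * ((t - 140) / 4.0) ** 2)
        )
        peaks = v.detect_peaks(trace, t, smooth_window=1)
        assert len(peaks) == 1
        assert peaks[0].time == pytest.approx(60.0, abs=1.0)

    def test_cohort_peak_counts_match_ground_truth(self, cohort_ph_and_peaks):
        (items, truths) = cohort_ph_and_peaks
        matched = 0
        for (tr, ph, peaks), gt in zip(items, truths):
            # a pulse maximum at the very window edge cannot form a local
            # maximum, so compare counts away from the edges
            margin = gt.pulse_fwhm / 2.0
            lo, hi = margin, tr.times[-1] - margin
            interior_truth = [t for t in gt.pulse_times if lo <= t <= hi]
            interior_det = [p for p in peaks if lo <= p.time <= hi]
            matched += len(interior_det) == len(interior_truth)
        assert matched / len(items) >= 0.95

    def test_min_separation_suppresses_double_calls(self):
        t = np.arange(60) * 2.0
        trace = np.exp(-0.5 * ((t - 50) / 5.0) ** 2) + np.exp(-0.5 * ((t - 60) / 5.0) ** 2)
        peaks = v.detect_peaks(trace, t, min_separation=20.0, smooth_window=1)
        assert len(peaks) == 1


class TestCycleMetrics:
    def test_hand_trace_deltas(self):
        t = np.arange(9, dtype=float)
        trace = np.array([5.8, 5.8, 6.2, 5.9, 5.8, 5.8, 6.3, 5.9, 5.8])
        peaks = v.detect_peaks(trace, t, min_separation=2.0, smooth_window=1)
        cm = v.cycle_metrics(trace, t, peaks, smooth_window=1)
        assert cm.peak_ph == pytest.approx([6.2, 6.3])
        assert cm.min_ph == pytest.approx([5.8, 5.8])
        assert cm.delta_ph == pytest.approx([0.4, 0.5])

    def test_single_peak_flat_baseline(self):
        t = np.arange(50) * 2.0
        trace = 5.8 + 0.4 * np.exp(-0.5 * ((t - 50) / 5.0) ** 2)
        peaks = v.detect_peaks(trace, t, smooth_window=1)
        cm = v.cycle_metrics(trace, t, peaks, smooth_window=1)
        assert cm.n_cycles == 1
        assert cm.delta_ph[0] == pytest.approx(trace.max() - 5.8, abs=1e-6)

    def test_default_cohort_recovers_printed_extremes(self, cohort_ph_and_peaks):
        (items, _) = cohort_ph_and_peaks
        mins, peaks_ph, deltas = [], [], []
        for tr, ph, peaks in items:
            cm = v.cycle_metrics(ph, tr.times, peaks)
            mins += list(cm.min_ph)
            peaks_ph += list(cm.peak_ph)
            deltas += list(cm.delta_ph)
        assert len(mins) >= 120
        assert np.mean(mins) == pytest.approx(5.82, abs=0.02)
        assert np.mean(peaks_ph) == pytest.approx(6.20, abs=0.02)
        assert np.mean(deltas) == pytest.approx(0.38, abs=0.02)

    def test_requires_a_peak(self):
        with pytest.raises(ValueError):
            v.cycle_metrics(np.zeros(10), np.arange(10.0), [])


class TestHalfWidth:
    def test_triangular_pulse(self):
        t = np.arange(101) * 1.0
        trace = np.clip(1.0 - np.abs(t - 50) / 10.0, 0.0, None)  # base width 20 min
        peaks = v.detect_peaks(trace, t, smooth_window=1)
        assert peaks[0].half_width == pytest.approx(10.0, abs=0.1)

    def test_gaussian_pulse_closed_form(self):
        sigma = 6.0
        t = np.arange(201) * 1.0
        trace = np.exp(-0.5 * ((t - 100) / sigma) ** 2)
        peaks = v.detect_peaks(trace, t, smooth_window=1)
        assert peaks[0].half_width == pytest.approx(2 * math.sqrt(2 * math.log(2)) * sigma, rel=0.02)

    def test_sdc_cohort_median_matches_generator_fwhm(self, cohort_ph_and_peaks):
        (items, _) = cohort_ph_and_peaks
        widths = [p.half_width for _, _, peaks in items for p in peaks]
        assert v.peak_halfwidth_summary(
            [p for _, _, peaks in items for p in peaks]
        ) == pytest.approx(11.0, abs=2.0)
        assert len(widths) >= 120

    def test_ynbd_pulses_floor_at_sampling_interval(self):
        cfg = v.cohort_config("YNBD", n_cells=30, seed=21)
        traces, truths = v.make_cohort(cfg)
        widths = []
        for tr, gt in zip(traces, truths):
            # YNBD pulses are at the sampling limit; smoothing would widen
            # them, so the detector runs on the raw trace
            ph_proxy = tr.channels["vsep"]
            for p in v.detect_peaks(ph_proxy, tr.times, smooth_window=1):
                widths.append(p.half_width)
        assert len(widths) > 50
        assert abs(np.median(widths) - 2.0) <= 2.0  # floor = dt


class TestAlignment:
    def _trace_with_peak_at(self, t0):
        t = np.arange(100) * 2.0
        vals = np.exp(-0.5 * ((t - t0) / 5.0) ** 2)
        return v.TraceSeries(cell_id=f"p{t0}", times=t, channels={"x": vals})

    def test_first_peak_moved_to_zero(self):
        traces = [self._trace_with_peak_at(0.0), self._trace_with_peak_at(137.0)]
        peaks = [
            [Peak(time=0.0, height=1, prominence=1, half_width=5, index=0)],
            [Peak(time=137.0, height=1, prominence=1, half_width=5, index=68)],
        ]
        aligned, n_excl = v.align_first_peak(traces, peaks)
        assert n_excl == 0
        assert aligned[0].times[0] == pytest.approx(0.0)
        assert aligned[1].times[0] == pytest.approx(-137.0)

    def test_peakless_trace_excluded_with_count(self):
        traces = [self._trace_with_peak_at(50.0), self._trace_with_peak_at(60.0)]
        peaks = [[Peak(time=50.0, height=1, prominence=1, half_width=5, index=25)], []]
        with pytest.warns(UserWarning):
            aligned, n_excl = v.align_first_peak(traces, peaks)
        assert len(aligned) == 1 and n_excl == 1


class TestEventIntervals:
    def _annotated_trace(self, buds, seps):
        t = np.arange(100) * 2.0
        return v.TraceSeries(
            cell_id="c",
            times=t,
            channels={"x": np.zeros(100)},
            events={"bud_emergence": buds, "separation": seps},
        )

    def test_hand_annotation_arithmetic(self):
        tr = self._annotated_trace([10.0], [75.0])
        peaks = [Peak(time=70.0, height=1, prominence=1, half_width=5, index=35)]
        iv = v.event_intervals([tr], [peaks])
        assert iv.bud_to_peak == pytest.approx([60.0])
        assert iv.peak_to_sep == pytest.approx([5.0])

    def test_peak_coincident_with_separation(self):
        tr = self._annotated_trace([10.0], [70.0])
        peaks = [Peak(time=70.0, height=1, prominence=1, half_width=5, index=35)]
        iv = v.event_intervals([tr], [peaks])
        assert iv.peak_to_sep == pytest.approx([0.0])

    def test_unmatched_peaks_skipped_and_counted(self):
        tr = self._annotated_trace([], [75.0])
        peaks = [Peak(time=70.0, height=1, prominence=1, half_width=5, index=35)]
        iv = v.event_intervals([tr], [peaks])
        assert len(iv.bud_to_peak) == 0 and iv.n_unmatched == 1

    def test_default_cohort_recovers_event_offsets(self, cohort_ph_and_peaks):
        (items, _) = cohort_ph_and_peaks
        iv = v.event_intervals([tr for tr, _, _ in items], [pk for _, _, pk in items])
        assert iv.mean_bud_to_peak == pytest.approx(59.4, abs=2.0)
        assert iv.mean_peak_to_sep == pytest.approx(5.7, abs=2.0)

    def test_timing_unbiased_at_moderate_noise(self):
        cfg = v.cohort_config("SDC", n_cells=12, seed=33, channels={"bcecf": v.BCECF, "ref": v.MCHERRY})
        cfg = replace(cfg, profile=replace(cfg.profile, noise_sd=0.05))
        traces, _ = v.make_cohort(cfg)
        series = v.make_calibration_series((v.BCECF, v.MCHERRY), seed=7)
        fit = v.fit_calibration(series, mode="sigmoid")
        peaks_per = []
        for tr in traces:
            ph, _ = v.ratio_to_ph(fit, tr.ratio("bcecf", "ref"))
            # 5x the noise needs a wider window and a stricter prominence cut
            peaks_per.append(
                v.detect_peaks(ph, tr.times, min_prominence_frac=0.4, smooth_window=7)
            )
        iv = v.event_intervals(traces, peaks_per)
        assert abs(iv.mean_bud_to_peak - 59.4) < 2.0


class TestDeltaRecoveryInvariant:
    def test_mean_delta_matches_profile_contrast(self, cohort_ph_and_peaks):
        (items, _) = cohort_ph_and_peaks
        deltas = []
        for tr, ph, peaks in items:
            deltas += list(v.cycle_metrics(ph, tr.times, peaks).delta_ph)
        assert np.mean(deltas) == pytest.approx(6.20 - 5.82, abs=0.02)
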