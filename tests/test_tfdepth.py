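"""In vivo tapered-fiber analysis: calibration, scan demodulation,
autofluorescence subtraction, binning, extrema and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plaquefp import synthgen, tfdepth
from plaquefp.stats import DegenerateInputError
from plaquefp.synthgen import level_voltages, simulate_dye_recording, simulate_recording
from plaquefp.tfdepth import (GalvoScanMatrix, ScanError, bin_timecourse,
                              calibrate_power, demodulate_scan, depth_profile_window,
                              extrema_depths, fit_autofluorescence, galvo_depth_map,
                              paired_extrema_test, subtract_af, zscore_trace)


class TestCalibratePower:
    def test_uniform_fluorescence_needs_uniform_power(self):
        cal = calibrate_power(np.full(41, 3.7))
        np.testing.assert_allclose(cal.PR, 1.0)

    def test_hand_computed_example(self):
        cal = calibrate_power([2.0, 1.0, 4.0])
        np.testing.assert_allclose(cal.PR, [2.0, 4.0, 1.0])

    def test_scale_invariance(self, rng):
        F = rng.uniform(0.5, 3.0, size=41)
        np.testing.assert_allclose(calibrate_power(F).PR,
                                   calibrate_power(17.0 * F).PR, atol=1e-12)

    def test_nonpositive_fluorescence_rejected(self):
        with pytest.raises(ValueError):
            calibrate_power([1.0, 0.0, 2.0])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_minimum_required_power_is_exactly_one(self, seed):
        F = np.random.default_rng(seed).uniform(0.1, 9.0, size=17)
        assert calibrate_power(F).PR.min() == 1.0

    def test_calibration_loop_equalizes_the_forward_model(self, tf_protocol):
        # nonuniform taper sensitivity -> dye measurement -> PR -> re-measure
        sens = 0.4 + 0.6 * np.sin(np.linspace(0.3, 2.8, 41)) ** 2
        rec = simulate_dye_recording(tf_protocol, sens)
        F0 = demodulate_scan(rec, tf_protocol).F[:, 0]
        cal = calibrate_power(F0)
        rec2 = simulate_dye_recording(tf_protocol, sens, power_per_level=cal.PR)
        F1 = demodulate_scan(rec2, tf_protocol).F[:, 0]
        assert F1.max() / F1.min() - 1.0 < 0.01


class TestDemodulateScan:
    def test_level_grid_spacing(self):
        lv = level_voltages(41)
        assert len(lv) == 41
        assert lv[1] - lv[0] == pytest.approx(0.1125)

    def test_noiseless_round_trip_matches_generator_truth(self, tf_protocol):
        dens = np.linspace(0.0, 300.0, 41)
        rec = simulate_recording(dens, tf_protocol, 1e-5, 1.0, 120.0, 60.0,
                                 0.0, 5, duration_s=300.0, gain=0.003)
        mat = demodulate_scan(rec, tf_protocol)
        truth = synthgen.scan_truth(rec.meta, mat.times_s)
        assert np.nanmax(np.abs(mat.F - truth)) < 1e-9

    def test_timepoint_value_is_mean_over_sweep_repetitions(self, tf_protocol):
        rec = simulate_recording(np.zeros(41), tf_protocol, 0.0, 2.0, np.inf, 1.0,
                                 0.0, 0, duration_s=60.0)
        base = demodulate_scan(rec, tf_protocol).F[:, 0]
        # shift every sample of the first of the 5 sweeps by +1
        det = rec.detector.copy()
        sweep_len = len(det) // tf_protocol.reps
        det[:sweep_len] += 1.0
        shifted = synthgen.RawRecording(t=rec.t, detector=det, sync=rec.sync,
                                        galvo=rec.galvo, meta=rec.meta)
        np.testing.assert_allclose(demodulate_scan(shifted, tf_protocol).F[:, 0],
                                   base + 1.0 / tf_protocol.reps, atol=1e-9)

    def test_negative_galvo_pulses_are_discarded(self, tf_protocol):
        rec = simulate_recording(np.zeros(41), tf_protocol, 0.0, 1.0, np.inf, 1.0,
                                 0.0, 0, duration_s=60.0)
        det = rec.detector.copy()
        det[rec.galvo < 0] = 1e6          # poison the sub-zero-voltage pulses
        poisoned = synthgen.RawRecording(t=rec.t, detector=det, sync=rec.sync,
                                         galvo=rec.galvo, meta=rec.meta)
        mat = demodulate_scan(poisoned, tf_protocol)
        assert np.nanmax(mat.F) < 2.0


class TestAutofluorescence:
    @staticmethod
    def matrix(F, times):
        return GalvoScanMatrix(levels_v=level_voltages(F.shape[0]),
                               times_s=times, F=F)

    def test_exact_line_recovered(self):
        t = np.linspace(0.0, 9000.0, 12)
        a, b = 2e-5, 1.3
        model = fit_autofluorescence(self.matrix(np.tile(a * t + b, (5, 1)), t))
        np.testing.assert_allclose(model.slopes, a, atol=1e-9)
        np.testing.assert_allclose(model.intercepts, b, atol=1e-9)
        assert np.all(model.cv_error < 1e-12)

    def test_constant_signal_gives_zero_slope(self):
        t = np.linspace(0.0, 3000.0, 8)
        model = fit_autofluorescence(self.matrix(np.full((3, 8), 4.2), t))
        np.testing.assert_allclose(model.slopes, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.intercepts, 4.2, atol=1e-9)

    def test_slope_sampling_error_matches_linear_estimator_theory(self):
        # the averaged two-fold estimator is linear in y: slope_hat = w @ y;
        # with noise sd sigma, slope_hat ~ N(a, sigma^2 ||w||^2)
        t = np.linspace(0.0, 12000.0, 20)
        sigma, a, b = 0.05, 3e-5, 1.0
        w = np.zeros((2, len(t)))
        for f, mask in enumerate((np.arange(20) % 2 == 0, np.arange(20) % 2 == 1)):
            tf_ = t[mask]
            X = np.column_stack([tf_, np.ones_like(tf_)])
            w[f, mask] = np.linalg.pinv(X)[0]
        se = sigma * np.linalg.norm(w.mean(axis=0))
        hits = 0
        for seed in range(200):
            y = a * t + b + np.random.default_rng(seed).normal(0, sigma, len(t))
            model = fit_autofluorescence(self.matrix(y[None, :], t))
            hits += abs(model.slopes[0] - a) <= 3.0 * se
        assert hits >= 190

    def test_too_few_timepoints_rejected(self):
        t = np.array([0.0, 100.0, 200.0])
        with pytest.raises(ScanError):
            fit_autofluorescence(self.matrix(np.ones((2, 3)), t))

    def test_self_subtraction_is_null(self):
        t = np.linspace(0.0, 6000.0, 10)
        F = np.outer(np.linspace(1e-5, 5e-5, 4), t) + 1.0
        mat = self.matrix(F, t)
        fm = subtract_af(mat, fit_autofluorescence(mat))
        assert np.nanmax(np.abs(fm.F)) < 1e-9

    def test_known_tracer_term_survives_subtraction(self):
        t = np.linspace(0.0, 6000.0, 10)
        af = np.outer(np.full(4, 2e-5), t) + 0.9
        tracer = np.outer([0.0, 0.1, 0.4, 0.2], 1.0 - np.exp(-t / 1800.0))
        day0 = self.matrix(af, t)
        day1 = self.matrix(af + tracer, t)
        fm = subtract_af(day1, fit_autofluorescence(day0))
        np.testing.assert_allclose(fm.F, tracer, atol=1e-9)


class TestBinning:
    def test_constant_signal_bins_to_constant(self):
        t = 30.0 + 60.0 * np.arange(30)
        mat = GalvoScanMatrix(levels_v=level_voltages(2), times_s=t,
                              F=np.full((2, 30), 5.5))
        binned = bin_timecourse(mat)
        assert binned.F.shape == (2, 6)
        np.testing.assert_allclose(binned.F, 5.5)

    def test_thirty_minutes_at_one_minute_sampling_gives_six_bins(self):
        t = 30.0 + 60.0 * np.arange(30)
        mat = GalvoScanMatrix(levels_v=level_voltages(1), times_s=t,
                              F=np.ones((1, 30)))
        assert bin_timecourse(mat, 300.0).F.shape[1] == 6

    def test_linear_ramp_bins_to_midpoint_values(self):
        t = 30.0 + 60.0 * np.arange(30)      # samples centered within bins
        c = 0.01
        mat = GalvoScanMatrix(levels_v=level_voltages(1), times_s=t,
                              F=(c * t)[None, :])
        binned = bin_timecourse(mat, 300.0)
        np.testing.assert_allclose(binned.F[0], c * binned.bin_mid_s, atol=1e-9)

    def test_partial_trailing_bin_flagged(self):
        t = 30.0 + 60.0 * np.arange(27)      # last bin only partly covered
        mat = GalvoScanMatrix(levels_v=level_voltages(1), times_s=t,
                              F=np.ones((1, 27)))
        assert bin_timecourse(mat, 300.0).partial_last


def _binned(F, bin_s=300.0):
    n_levels, n_bins = F.shape
    return tfdepth.BinnedMatrix(levels_v=level_voltages(n_levels),
                                bin_mid_s=(np.arange(n_bins) + 0.5) * bin_s,
                                F=F, bin_s=bin_s)


class TestExtremaAndTraces:
    def test_largest_plateau_level_is_max(self):
        F = np.tile(np.linspace(0.0, 1.0, 50), (5, 1))
        F[3] += 2.0
        F[1] -= 2.0
        ext = extrema_depths(_binned(F))
        assert ext["max_level"] == 3 and ext["min_level"] == 1

    def test_ties_break_toward_lower_level(self):
        ext = extrema_depths(_binned(np.ones((4, 50))))
        assert ext["max_level"] == 0 and ext["min_level"] == 0

    def test_matches_brute_force_median_scan(self, rng):
        for _ in range(100):
            F = rng.normal(size=(6, 50))
            ext = extrema_depths(_binned(F))
            sel = (np.arange(50) + 0.5) * 5.0
            window = (sel >= 30.0) & (sel <= 240.0)
            med = np.median(F[:, window], axis=1)
            assert ext["max_level"] == int(np.argmax(med))
            assert ext["min_level"] == int(np.argmin(med))

    def test_empty_window_rejected(self):
        with pytest.raises(ScanError):
            extrema_depths(_binned(np.ones((2, 3))), window_min=(500.0, 600.0))

    def test_zscore_trace_hand_worked(self):
        trace = np.array([[1.0, 2.0, 3.0, 2.0, 2.0, 10.0, 4.0, 6.0]])
        dF = zscore_trace(_binned(trace), level=0, smooth_window=1)
        f0 = trace[0, :5]          # bins with midpoints inside 25 min
        expected = (trace[0] - f0.mean()) / f0.std(ddof=1)
        np.testing.assert_allclose(dF, expected, atol=1e-12)

    def test_zscore_trace_affine_invariance(self):
        trace = np.sin(np.arange(10.0))[None, :]
        base = zscore_trace(_binned(trace), 0)
        scaled = zscore_trace(_binned(4.0 * trace + 2.0), 0)
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_zero_baseline_variance_rejected(self):
        trace = np.concatenate([np.ones(5), [2.0, 3.0]])[None, :]
        with pytest.raises(DegenerateInputError):
            zscore_trace(_binned(trace), 0)


class TestDepthProfileWindow:
    def test_constant_in_time_profile_equals_any_bin(self):
        prof_vals = np.linspace(0.0, 2.0, 41)
        F = np.tile(prof_vals[:, None], (1, 50))
        prof = depth_profile_window(_binned(F))
        np.testing.assert_allclose(prof.values, prof_vals, atol=1e-12)

    def test_window_outside_recording_rejected(self):
        with pytest.raises(ScanError):
            depth_profile_window(_binned(np.ones((41, 10))))  # only 50 min long

    def test_depth_map_spans_the_active_length(self):
        depths = galvo_depth_map(level_voltages(41), entry_depth_um=1200.0)
        assert depths[0] == 1200.0
        assert depths[-1] == pytest.approx(1200.0 + 1580.0)
        assert depths[1] - depths[0] == pytest.approx(39.5)

    def test_orientation_flip_reverses_the_map(self):
        lv = level_voltages(41)
        down = galvo_depth_map(lv)
        up = galvo_depth_map(lv, orientation=-1)
        np.testing.assert_allclose(up, down[::-1], atol=1e-9)

    def test_track_shift_translates_stations(self):
        lv = level_voltages(5)
        np.testing.assert_allclose(galvo_depth_map(lv, shift_um=-600.0),
                                   galvo_depth_map(lv) - 600.0)


class TestPairedExtrema:
    def test_identical_pairs_are_null(self):
        with pytest.warns(UserWarning):
            res = paired_extrema_test(np.ones(8), np.ones(8))
        assert res.p == 1.0

    def test_uniform_positive_gap_exact_p(self):
        x = np.arange(8.0)
        assert paired_extrema_test(x + 1.0, x).p == pytest.approx(2 / 256)
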