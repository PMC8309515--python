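"""Evaluation metrics: definitional oracles, peak detection, paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imukin import metrics, synthetic
from imukin.metrics import (DegenerateTestError, PeakEventSeries,
                            UndefinedMetricError, detect_peaks, match_peaks,
                            normalized, paired_comparison, peak_rmse_std,
                            r_squared, rom, schober_label)

from conftest import gait_slice


class TestRSquared:
    def test_identity_is_one(self):
        y = np.array([1.0, 5.0, 2.0, 8.0])
        assert r_squared(y, y) == 1.0

    def test_mean_predictor_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, np.full(4, y.mean())) == 0.0

    def test_hand_computed_example(self):
        # SSres = 1, SStot = 2
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_actual_raises(self):
        with pytest.raises(UndefinedMetricError):
            r_squared(np.ones(5), np.arange(5.0))


class TestRomAndNormalization:
    def test_rom_example(self):
        assert rom([20.0, 140.0, 60.0]) == 120.0

    def test_rom_constant_is_zero_and_normalization_then_errors(self):
        assert rom(np.full(4, 7.0)) == 0.0
        with pytest.raises(UndefinedMetricError):
            normalized(1.0, 0.0)

    def test_percentages(self):
        assert normalized(5.0, 50.0) == pytest.approx(10.0)
        assert normalized(0.0, 50.0) == 0.0
        assert normalized(4.4, 88.7) == pytest.approx(4.96, abs=0.01)


class TestPeakRmseStd:
    def test_equal_residuals(self):
        rmse, std = peak_rmse_std([1.0, 1.0], [0.0, 0.0])
        assert rmse == pytest.approx(1.0)
        assert std == pytest.approx(0.0)

    def test_hand_computed_spread(self):
        rmse, std = peak_rmse_std([0.0, 2.0], [0.0, 0.0])
        assert rmse == pytest.approx(np.sqrt(2.0))
        assert std == pytest.approx(np.sqrt(2.0))  # ddof=1

    def test_symmetric_residuals(self):
        rmse, _ = peak_rmse_std([-3.0, 3.0], [0.0, 0.0])
        assert rmse == pytest.approx(3.0)

    def test_no_pairs_raises(self):
        with pytest.raises(UndefinedMetricError):
            peak_rmse_std([], [])


class TestOracleEquivalence:
    def test_brute_force_recomputation_on_random_traces(self):
        """R², RMSE, STD, ROM, NRMSE, NSTD match their definitions to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            y = rng.normal(scale=10.0, size=n)
            yhat = y + rng.normal(scale=2.0, size=n)
            # brute-force from the printed formulas
            ss_res = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
            ss_tot = sum((yi - np.mean(y)) ** 2 for yi in y)
            assert abs(r_squared(y, yhat) - (1 - ss_res / ss_tot)) < 1e-10
            assert abs(rom(y) - (max(y) - min(y))) < 1e-10
            r = y - yhat
            rmse_bf = (sum(ri ** 2 for ri in r) / n) ** 0.5
            mean_r = sum(r) / n
            std_bf = (sum((ri - mean_r) ** 2 for ri in r) / (n - 1)) ** 0.5
            rmse, std = peak_rmse_std(y, yhat)
            assert abs(rmse - rmse_bf) < 1e-10
            assert abs(std - std_bf) < 1e-10
            rom_v = rom(y)
            assert abs(normalized(rmse, rom_v) - 100 * rmse_bf / rom_v) < 1e-10
            assert abs(normalized(std, rom_v) - 100 * std_bf / rom_v) < 1e-10

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_property(self, k):
        """Scaling both traces by k scales the degree metrics by k and leaves
        the dimensionless ones unchanged."""
        rng = np.random.default_rng(7)
        y = rng.normal(scale=5.0, size=30)
        yhat = y + rng.normal(size=30)
        rmse, std = peak_rmse_std(y, yhat)
        rmse_k, std_k = peak_rmse_std(k * y, k * yhat)
        assert rmse_k == pytest.approx(k * rmse, rel=1e-9)
        assert std_k == pytest.approx(k * std, rel=1e-9)
        assert rom(k * y) == pytest.approx(k * rom(y), rel=1e-9)
        assert r_squared(k * y, k * yhat) == pytest.approx(r_squared(y, yhat), rel=1e-9)
        assert normalized(rmse_k, rom(k * y)) == pytest.approx(
            normalized(rmse, rom(y)), rel=1e-9)


class TestDetectPeaks:
    def test_two_bump_knee_trace_recovers_stance_values(self):
        t = np.arange(0, 8.0, 0.01)
        phase = (t / 0.8) % 1.0
        trace = 10.0 + 15.0 * np.exp(-0.5 * ((phase - 0.2) / 0.07) ** 2) \
            + 60.0 * np.exp(-0.5 * ((phase - 0.65) / 0.1) ** 2)
        events = detect_peaks(trace, "knee")
        assert len(events.times) >= 8
        np.testing.assert_allclose(events.values, 25.0, atol=0.1)

    def test_monotone_ramp_yields_no_knee_events(self):
        events = detect_peaks(np.linspace(0, 50, 400), "knee")
        assert len(events.times) == 0

    def test_hip_sinusoid_events_at_mean_plus_amplitude(self):
        t = np.arange(0, 6.0, 0.01)
        trace = 12.0 + 30.0 * np.sin(2 * np.pi * t / 0.75)
        events = detect_peaks(trace, "hip")
        assert len(events.times) == pytest.approx(8, abs=1)
        np.testing.assert_allclose(events.values, 42.0, atol=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.zeros(150), "knee")

    def test_full_recall_on_noise_free_simulator_output(self, quiet_profile):
        """Every injected stance and hip peak is found within 1 sample / 0.1 deg."""
        import dataclasses
        _, kin = synthetic.simulate_session(
            quiet_profile, synthetic.LEVEL_GROUND, 2.5, 40.0, seed=2,
            knee_amp_cv=0.0, hip_amp_cv=0.0)
        knee = gait_slice(kin, "knee")
        hip = gait_slice(kin, "hip")
        from scipy.signal import find_peaks
        span_k = knee.max() - knee.min()
        truth_all, _ = find_peaks(knee, prominence=0.01 * span_k)
        mid = knee.min() + 0.5 * span_k
        truth_stance = truth_all[knee[truth_all] < mid]
        truth_swing = truth_all[knee[truth_all] >= mid]
        got = detect_peaks(knee, "knee")
        got_idx = np.round(got.times * 100).astype(int)
        # the detector delimits cycles by swing peaks, so only stance events
        # between the first and last swing peak are recoverable
        covered = truth_stance[(truth_stance > truth_swing[0])
                               & (truth_stance < truth_swing[-1])]
        assert len(got_idx) == len(covered)
        assert np.max(np.abs(got_idx - covered)) <= 1
        assert np.max(np.abs(got.values - knee[covered])) <= 0.1

        truth_hip, _ = find_peaks(hip, prominence=0.3 * (hip.max() - hip.min()))
        got_hip = detect_peaks(hip, "hip")
        got_hidx = np.round(got_hip.times * 100).astype(int)
        assert len(got_hidx) == len(truth_hip)
        assert np.max(np.abs(got_hidx - truth_hip)) <= 1
        assert np.max(np.abs(got_hip.values - hip[truth_hip])) <= 0.1


def _events(times, values, joint="knee"):
    return PeakEventSeries(joint=joint, event_kind="knee_stance_peak",
                           times=np.asarray(times, float),
                           values=np.asarray(values, float))


class TestMatchPeaks:
    def test_identical_series_all_matched(self):
        a = _events([1.0, 2.0, 3.0], [25.0, 26.0, 24.0])
        va, vp, unmatched = match_peaks(a, a)
        np.testing.assert_array_equal(va, vp)
        assert unmatched == 0

    def test_small_shift_matches_counterparts(self):
        a = _events([1.0, 2.0, 3.0], [25.0, 26.0, 24.0])
        b = _events([1.1, 2.1, 3.1], [24.5, 25.5, 23.5])
        va, vp, unmatched = match_peaks(a, b)
        assert unmatched == 0
        np.testing.assert_array_equal(va, a.values)
        np.testing.assert_array_equal(vp, b.values)

    def test_large_shift_matches_nothing(self):
        a = _events([1.0, 2.0], [25.0, 26.0])
        b = _events([1.4, 2.4], [25.0, 26.0])
        va, _, unmatched = match_peaks(a, b)
        assert va.size == 0 and unmatched == 4

    def test_each_event_used_once(self):
        a = _events([1.0, 1.2], [25.0, 26.0])
        b = _events([1.1], [24.0])
        va, vp, unmatched = match_peaks(a, b)
        assert va.size == 1 and unmatched == 1


class TestPairedComparison:
    def test_closed_form_worked_example(self):
        cmp_res = paired_comparison([0.93, 0.85], [0.96, 0.90], "r2")
        assert cmp_res.t_statistic == pytest.approx(-4.0, abs=1e-9)
        # closed form for df=1: p = 1 - 2*atan(|t|)/pi
        p_closed = 1.0 - 2.0 * np.arctan(4.0) / np.pi
        assert cmp_res.p_value == pytest.approx(p_closed, abs=1e-9)
        assert not cmp_res.significant

    def test_independent_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=8)
        g = a + rng.normal(size=8) * 0.3 + 0.2
        ours = paired_comparison(a, g, "rmse")
        t_ref, p_ref = stats.ttest_1samp(a - g, 0.0)
        assert ours.t_statistic == pytest.approx(t_ref, rel=1e-12)
        assert ours.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_zero_variance_differences_raise(self):
        with pytest.raises(DegenerateTestError):
            paired_comparison([0.9, 0.8], [0.9, 0.8], "r2")

    def test_r2_labels_attached(self):
        cmp_res = paired_comparison([0.86, 0.83], [0.96, 0.92], "r2")
        assert cmp_res.r2_interpretation == ("strong", "very strong")


class TestSchoberLabels:
    @pytest.mark.parametrize("value,label", [
        (0.05, "negligible"), (0.25, "weak"), (0.55, "moderate"),
        (0.85, "strong"), (0.95, "very strong"),
        (-0.85, "strong"), (1.0, "very strong"),
    ])
    def test_bins(self, value, label):
        assert schober_label(value) == label


class TestEvaluateTrace:
    def test_report_identities_hold(self, quiet_profile):
        _, kin = synthetic.simulate_session(
            quiet_profile, synthetic.LEVEL_GROUND, 2.5, 40.0, seed=6)
        knee = gait_slice(kin, "knee")
        rng = np.random.default_rng(0)
        predicted = knee + rng.normal(scale=1.0, size=knee.size)
        rep = metrics.evaluate_trace(knee, predicted, "knee")
        assert rep.nrmse == pytest.approx(100 * rep.rmse / rep.rom, rel=1e-12)
        assert rep.nstd == pytest.approx(100 * rep.std / rep.rom, rel=1e-12)
        assert rep.rom == pytest.approx(knee.max() - knee.min())
        assert rep.r2 <= 1.0
        assert rep.n_peaks_matched > 0
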