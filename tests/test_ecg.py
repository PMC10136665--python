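"""QRS detection, RR correction and the cardiac feature estimators."""

import numpy as np
import pytest

from odorans import (
    ECGRecord,
    correct_rr,
    detect_qrs,
    extract_hrv,
    simulate_rr_series,
    synthesize_ecg,
)
from odorans.ecg import (
    RRSeries,
    FLAG_CORRECTED,
    FLAG_NORMAL,
    hrv_features,
    poincare_features,
    spectral_features,
    time_domain_features,
)
from odorans.errors import (
    ConfigurationError,
    InsufficientDataError,
    UnreliableSeriesError,
    UnusableRecordError,
    WindowTooShortError,
)


def _series(intervals, t0=0.0):
    return RRSeries.from_intervals(intervals, t0)


class TestDetectQRS:
    def test_noise_free_beats_within_2ms(self):
        rr = simulate_rr_series(72, 0.02, 0, 0, duration=30, seed=0)
        ecg = synthesize_ecg(rr, fs=500, noise_sd=0.0, seed=0)
        det = detect_qrs(ecg)
        truth = ecg.meta["beat_times"]
        assert det.n_beats == len(truth)
        assert np.max(np.abs(det.beat_times - truth)) < 0.002

    def test_flat_record_unusable(self):
        with pytest.raises(UnusableRecordError):
            detect_qrs(ECGRecord(np.zeros(500 * 15), 500))

    def test_saturated_record_unusable(self):
        x = np.clip(5 * np.sin(2 * np.pi * 1.2 * np.arange(500 * 15) / 500), -1, 1)
        with pytest.raises(UnusableRecordError):
            detect_qrs(ECGRecord(x, 500))

    def test_short_record_unusable(self):
        with pytest.raises(UnusableRecordError):
            detect_qrs(ECGRecord(np.random.default_rng(0).normal(size=500 * 5), 500))

    def test_low_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_qrs(ECGRecord(np.zeros(200 * 15), 200))

    def test_moderate_noise_high_sensitivity_precision(self):
        rr = simulate_rr_series(75, 0.03, 2e-4, 2e-4, duration=60, seed=1)
        ecg = synthesize_ecg(rr, fs=500, noise_sd=0.08, seed=1)
        det = detect_qrs(ecg)
        truth = ecg.meta["beat_times"]
        tp = sum(np.min(np.abs(truth - t)) < 0.05 for t in det.beat_times)
        assert tp / len(det.beat_times) >= 0.99   # precision
        assert tp / len(truth) >= 0.99            # sensitivity


class TestCorrectRR:
    def test_clean_series_unchanged(self):
        rr = simulate_rr_series(70, 0.02, 0, 0, duration=120, seed=2)
        out = correct_rr(rr)
        np.testing.assert_array_equal(out.intervals, rr.intervals)
        assert out.fraction_corrected == 0.0
        assert np.all(out.flags == FLAG_NORMAL)

    def test_missed_beat_split_others_untouched(self):
        intervals = np.full(100, 0.8)
        intervals[50] = 1.6  # one beat missed -> doubled interval
        out = correct_rr(_series(intervals))
        assert len(out.intervals) == 101
        np.testing.assert_allclose(out.intervals, 0.8)
        assert np.flatnonzero(out.flags == FLAG_CORRECTED).tolist() == [50, 51]
        assert np.all(np.diff(out.beat_times) > 0)

    def test_isolated_outlier_replaced_by_local_median(self):
        intervals = np.full(60, 0.8)
        intervals[30] = 1.0  # 25% deviation, not a doubling
        out = correct_rr(_series(intervals))
        assert out.intervals[30] == pytest.approx(0.8)
        assert out.flags[30] == FLAG_CORRECTED
        assert out.fraction_corrected == pytest.approx(1 / 60)

    def test_too_many_artifacts_unreliable(self):
        rng = np.random.default_rng(3)
        intervals = np.full(100, 0.8)
        bad = rng.choice(100, size=25, replace=False)
        intervals[bad] = 1.3
        with pytest.raises(UnreliableSeriesError):
            correct_rr(_series(intervals))

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            correct_rr(_series(np.full(5, 0.8)))


class TestTimeDomain:
    def test_constant_intervals(self):
        f = time_domain_features(_series(np.full(30, 0.8)))
        assert f.hr == pytest.approx(75.0)
        assert f.rmssd == 0.0
        assert f.nn50 == 0

    def test_alternating_60ms_differences(self):
        intervals = np.array([0.80, 0.86] * 11)[:21]
        f = time_domain_features(_series(intervals))
        assert f.rmssd == pytest.approx(0.060, abs=1e-12)
        assert f.nn50 == 20

    def test_exact_50ms_tie_not_counted(self):
        intervals = np.array([0.80, 0.85] * 11)[:21]
        f = time_domain_features(_series(intervals))
        assert f.nn50 == 0

    def test_insufficient_intervals(self):
        with pytest.raises(InsufficientDataError):
            time_domain_features(_series([0.8, 0.8]))

    def test_corrected_intervals_enter_hr_but_not_differences(self):
        intervals = np.full(60, 0.8)
        intervals[30] = 1.2
        out = correct_rr(_series(intervals))
        f = time_domain_features(out)
        assert f.hr == pytest.approx(75.0)
        assert f.rmssd == 0.0  # pairs touching the repaired beat are excluded


class TestPoincare:
    def test_constant_series_undefined_indices(self):
        f = poincare_features(_series(np.full(30, 0.8)))
        assert f.sd1 == 0.0 and f.sd2 == 0.0
        assert np.isnan(f.csi) and np.isnan(f.cvi)

    def test_white_noise_cloud_is_isotropic(self):
        """For i.i.d. intervals the Poincare cloud is round: CSI -> 1."""
        csis = [
            poincare_features(
                simulate_rr_series(70, 0.03, 0, 0, duration=600, seed=s)
            ).csi
            for s in range(20)
        ]
        assert np.mean(csis) == pytest.approx(1.0, abs=0.05)

    def test_projections_match_explicit_rotation(self):
        """Brute-force oracle: rotate the scatter by 45 deg with a rotation
        matrix and take coordinate standard deviations."""
        rng = np.random.default_rng(7)
        theta = np.pi / 4
        R = np.array(
            [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
        )
        for _ in range(50):
            intervals = 0.8 + 0.05 * rng.standard_normal(rng.integers(10, 200))
            f = poincare_features(_series(intervals))
            pts = np.stack([intervals[:-1], intervals[1:]])
            rot = R @ pts
            assert f.sd2 == pytest.approx(np.std(rot[0]), rel=1e-12)
            assert f.sd1 == pytest.approx(np.std(rot[1]), rel=1e-12)

    def test_variance_partition_identity(self):
        rng = np.random.default_rng(8)
        intervals = 0.8 + 0.04 * rng.standard_normal(300)
        f = poincare_features(_series(intervals))
        lhs = f.sd1**2 + f.sd2**2
        rhs = np.var(intervals[:-1]) + np.var(intervals[1:])
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_cvi_millisecond_convention_offset(self):
        rng = np.random.default_rng(9)
        intervals = 0.8 + 0.04 * rng.standard_normal(100)
        s = _series(intervals)
        f_s = poincare_features(s, units="s")
        f_ms = poincare_features(s, units="ms")
        assert f_ms.cvi == pytest.approx(f_s.cvi + 6.0, rel=1e-9)


class TestSpectral:
    def _tone_series(self, freq, amp=0.05, duration=300.0):
        times = [0.0]
        while times[-1] < duration:
            t = times[-1]
            times.append(t + 0.8 + amp * np.sin(2 * np.pi * freq * t))
        return RRSeries.from_beat_times(times)

    def test_lf_tone_confined_and_power_matches_analytic(self):
        rr = self._tone_series(0.10)
        f = spectral_features(rr)
        assert f.lf / (f.lf + f.hf) >= 0.90
        assert f.lf == pytest.approx(0.05**2 / 2, rel=0.10)
        assert f.lf_hf > 5

    def test_hf_tone_confined(self):
        rr = self._tone_series(0.25)
        f = spectral_features(rr)
        assert f.hf / (f.lf + f.hf) >= 0.90
        assert f.hf == pytest.approx(0.05**2 / 2, rel=0.10)
        assert f.lf_hf < 0.2

    def test_zero_variance_no_power(self):
        f = spectral_features(_series(np.full(200, 0.8)))
        assert f.lf == 0.0 and f.hf == 0.0
        assert np.isnan(f.lf_hf)

    def test_short_window_rejected_in_welch_mode(self):
        rr = simulate_rr_series(70, 0.02, 0, 0, duration=40, seed=0)
        with pytest.raises(WindowTooShortError):
            spectral_features(rr, (0.0, 40.0), mode="welch")

    def test_lombscargle_short_window_hf_tone(self):
        rr = self._tone_series(0.25, duration=60.0)
        f = spectral_features(rr, (0.0, 30.0), mode="lombscargle")
        assert f.hf > f.lf

    def test_total_power_tracks_tachogram_variance(self):
        rr = simulate_rr_series(70, 0.0, 4e-4, 4e-4, duration=600, seed=11)
        f = spectral_features(rr)
        assert f.lf + f.hf == pytest.approx(np.var(rr.intervals), rel=0.25)


class TestComposition:
    def test_extract_equals_manual_stage_composition(self):
        rr = simulate_rr_series(72, 0.02, 2e-4, 2e-4, duration=120, seed=5)
        ecg = synthesize_ecg(rr, fs=500, noise_sd=0.05, seed=5)
        via_extract = extract_hrv(ecg, [(0.0, 120.0)])[0]
        manual = hrv_features(correct_rr(detect_qrs(ecg)), (0.0, 120.0))
        assert via_extract.to_dict() == pytest.approx(manual.to_dict(), nan_ok=True)

    def test_missed_beat_artifact_recovered_within_1pct(self):
        rr = simulate_rr_series(70, 0.02, 0, 0, duration=180, seed=6)
        clean = correct_rr(rr)
        # drop one beat -> doubled interval at the removal point
        times = np.delete(rr.beat_times, 100)
        damaged = correct_rr(RRSeries.from_beat_times(times))
        f0 = time_domain_features(clean)
        f1 = time_domain_features(damaged)
        assert f1.hr == pytest.approx(f0.hr, rel=0.01)
        assert f1.rmssd == pytest.approx(f0.rmssd, rel=0.01)

    def test_detector_correction_end_to_end_hr_error(self):
        """2% injected missed/spurious beats: median |HR error| < 0.5 bpm."""
        rng = np.random.default_rng(12)
        errors = []
        for seed in range(40):
            rr = simulate_rr_series(72, 0.025, 0, 0, duration=60, seed=seed)
            times = rr.beat_times
            n = len(times)
            drop = rng.choice(np.arange(5, n - 5), size=max(1, n // 100), replace=False)
            kept = np.delete(times, drop)
            spur = rng.uniform(kept[2], kept[-3], size=max(1, n // 100))
            damaged = np.unique(np.concatenate([kept, spur]))
            gap_ok = np.concatenate([[True], np.diff(damaged) > 0.25])
            damaged = damaged[gap_ok]
            est = time_domain_features(correct_rr(RRSeries.from_beat_times(damaged)))
            true_hr = 60.0 / np.mean(rr.intervals)
            errors.append(abs(est.hr - true_hr))
        assert np.median(errors) < 0.5
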