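"""ECG detection, RR correction, segmentation and resampling tests."""

import numpy as np
import pytest
from scipy.signal import periodogram

from npsampen.cohort import synth_ecg, synth_rr, CohortSpec
from npsampen.preprocess import (
    DetectionError,
    ECGRecord,
    RRSeries,
    correct_rr_local_median,
    detect_r_peaks,
    resample_2hz,
    rr_from_peaks,
    segment_minutes,
)


def _match_rate(detected_s, truth_s, tol=0.05):
    """Fraction of true beats with a detection within tol seconds."""
    hits = sum(np.min(np.abs(detected_s - t)) <= tol for t in truth_s)
    return hits / len(truth_s)


class TestDetectRPeaks:
    def test_recovers_known_beats_in_noisy_ecg(self):
        rng = np.random.default_rng(0)
        # 5 minutes of mildly irregular beats around 0.9 s
        bt = np.cumsum(rng.uniform(0.7, 1.1, size=330))
        bt = bt[bt < 300]
        ecg, truth = synth_ecg(bt, fs=100.0, noise_sd=0.05, seed=1)
        peaks = detect_r_peaks(ecg)
        det_s = peaks / ecg.fs
        assert _match_rate(det_s, truth) >= 0.99

    def test_regular_1hz_train_gives_unit_rr(self):
        bt = np.arange(1.0, 61.0)  # beats at exactly 1 Hz
        ecg, _ = synth_ecg(bt, fs=100.0, noise_sd=0.0, seed=0)
        peaks = detect_r_peaks(ecg)
        rr = np.diff(peaks) / ecg.fs
        assert np.all(np.abs(rr - 1.0) <= 1.0 / ecg.fs + 1e-9)

    def test_flat_signal_raises(self):
        with pytest.raises(DetectionError):
            detect_r_peaks(ECGRecord(samples=np.zeros(2000), fs=100.0))

    def test_short_record_raises(self):
        with pytest.raises(DetectionError):
            detect_r_peaks(ECGRecord(samples=np.random.default_rng(0).normal(size=500), fs=100.0))


class TestRRFromPeaks:
    def test_simple_conversion(self):
        rr = rr_from_peaks([0, 100, 200], fs=100.0)
        np.testing.assert_allclose(rr.intervals, [1.0, 1.0])
        rr = rr_from_peaks([0, 50], fs=100.0)
        np.testing.assert_allclose(rr.intervals, [0.5])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            rr_from_peaks([0, 100, 90], fs=100.0)
        with pytest.raises(ValueError):
            rr_from_peaks([42], fs=100.0)


class TestLocalMedianCorrection:
    def test_clean_series_untouched(self):
        bt = np.arange(0.0, 20.0)
        rr = RRSeries(beat_times=bt, intervals=np.diff(bt))
        out = correct_rr_local_median(rr)
        np.testing.assert_array_equal(out.intervals, rr.intervals)
        assert not out.corrected.any()

    def test_single_spike_replaced_by_local_median(self):
        iv = np.array([1.0] * 5 + [0.4] + [1.0] * 5)
        bt = np.concatenate([[0.0], np.cumsum(iv)])
        out = correct_rr_local_median(RRSeries(bt, iv), window=5, tolerance=0.2)
        assert out.intervals[5] == pytest.approx(1.0)
        assert out.corrected.sum() == 1 and out.corrected[5]
        # beat times rebuilt by cumulative sum
        np.testing.assert_allclose(np.diff(out.beat_times), out.intervals)

    def test_injected_spikes_all_flagged_few_false_positives(self):
        rng = np.random.default_rng(4)
        n = 600
        iv = rng.normal(0.9, 0.02, size=n)
        spikes = rng.choice(n, size=30, replace=False)  # 5%
        iv[spikes] *= rng.choice([0.45, 1.8], size=30)
        bt = np.concatenate([[0.0], np.cumsum(iv)])
        out = correct_rr_local_median(RRSeries(bt, iv), window=5, tolerance=0.2)
        assert out.corrected[spikes].all()
        false = np.setdiff1d(np.flatnonzero(out.corrected), spikes)
        assert false.size < 0.01 * n

    def test_invalid_window(self):
        rr = RRSeries(np.arange(5.0), np.ones(4))
        with pytest.raises(ValueError):
            correct_rr_local_median(rr, window=4)


class TestSegmentation:
    def _constant_rr(self, hours=6.0, rr=1.0):
        bt = np.arange(0.0, hours * 3600 + rr, rr)
        return RRSeries(beat_times=bt, intervals=np.diff(bt))

    def test_six_hours_of_1s_beats(self):
        slices = segment_minutes(self._constant_rr())
        assert len(slices) == 360
        assert all(s.valid for s in slices)
        assert all(59 <= s.intervals.size <= 61 for s in slices)

    def test_half_open_minute_boundary(self):
        # interval ending exactly at t=60 belongs to minute 1
        bt = np.array([59.0, 60.0, 61.0])
        slices = segment_minutes(RRSeries(bt, np.diff(bt)), hours=2 / 60, min_beats=1)
        assert 60.0 in slices[1].times and 60.0 not in slices[0].times

    def test_every_interval_assigned_once(self):
        rng = np.random.default_rng(8)
        iv = rng.uniform(0.6, 1.2, size=2000)
        bt = np.concatenate([[0.0], np.cumsum(iv)])
        slices = segment_minutes(RRSeries(bt, iv), hours=0.5)
        total = sum(s.intervals.size for s in slices)
        in_span = np.sum(bt[1:] < 0.5 * 3600)
        assert total == in_span

    def test_short_record_yields_fewer_segments(self, caplog):
        slices = segment_minutes(self._constant_rr(hours=3.0), hours=6.0)
        assert len(slices) == 180

    def test_sparse_minute_marked_invalid(self):
        bt = np.array([0.0, 20.0, 40.0, 59.0, 61.0, 62.0])
        slices = segment_minutes(RRSeries(bt, np.diff(bt)), hours=1 / 60, min_beats=30)
        assert not slices[0].valid


class TestResample:
    def test_constant_intervals_resample_exactly(self):
        bt = np.arange(0.0, 62.0)
        sl = segment_minutes(RRSeries(bt, np.diff(bt)), hours=1 / 60)[0]
        seg = resample_2hz(sl)
        assert seg.valid and seg.samples.size == 120
        np.testing.assert_allclose(seg.samples, 1.0)

    def test_linear_ramp_reproduced_in_interior(self):
        # tachogram values exactly linear in time: the spline must reproduce
        # the line through the interior of the minute
        from npsampen.preprocess import MinuteSlice

        times = np.sort(np.random.default_rng(2).uniform(0.0, 60.0, size=65))
        intervals = 0.8 + 0.002 * times
        sl = MinuteSlice(minute=0, times=times, intervals=intervals, valid=True)
        seg = resample_2hz(sl)
        grid = np.arange(120) / 2.0
        interior = (grid > times[0]) & (grid < times[-1])
        np.testing.assert_allclose(
            seg.samples[interior], 0.8 + 0.002 * grid[interior], atol=1e-6
        )

    def test_sinusoidal_tachogram_keeps_dominant_frequency(self):
        spec = CohortSpec(seed=0)
        rng = np.random.default_rng(0)
        # respiratory-band oscillation at 0.1 Hz with tiny noise
        t, times = 0.0, [0.0]
        while t < 65:
            t += 0.9 + 0.05 * np.sin(2 * np.pi * 0.1 * t)
            times.append(t)
        bt = np.asarray(times)
        sl = segment_minutes(RRSeries(bt, np.diff(bt)), hours=1 / 60)[0]
        seg = resample_2hz(sl)
        f, p = periodogram(seg.samples - seg.samples.mean(), fs=2.0)
        assert f[np.argmax(p)] == pytest.approx(0.1, abs=0.03)

    def test_invalid_slice_propagates(self):
        bt = np.array([0.0, 30.0, 59.0, 60.5])
        sl = segment_minutes(RRSeries(bt, np.diff(bt)), hours=1 / 60, min_beats=30)[0]
        seg = resample_2hz(sl)
        assert not seg.valid and seg.samples.size == 0
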