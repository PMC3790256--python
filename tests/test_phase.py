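"""Cardiac/respiratory phase assignment and HR/RVT series."""

import numpy as np
import pytest

from pnmkit import (
    PeakTrain,
    PhysioRecording,
    cardiac_phase_at,
    heart_rate_series,
    respiratory_phase_at,
    rvt_series,
)
from pnmkit.errors import DegenerateSignalError, PeakDetectionError


def sinusoid_recording(duration=60.0, fs=50.0, period=4.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    resp = amplitude * np.sin(2 * np.pi * t / period)
    return PhysioRecording(fs, t, np.cos(2 * np.pi * t), resp)


class TestCardiacPhase:
    def test_zero_at_peaks_and_pi_at_midpoints(self):
        peaks = PeakTrain(np.array([0.0, 1.0, 2.0, 3.0]))
        assert cardiac_phase_at(np.array([0.0, 1.0, 2.0]), peaks) == pytest.approx([0, 0, 0])
        assert cardiac_phase_at(np.array([0.5, 1.5]), peaks) == pytest.approx([np.pi, np.pi])

    def test_irregular_interval_interpolation(self):
        peaks = PeakTrain(np.array([0.0, 1.0, 2.2]))
        phi = cardiac_phase_at(np.array([1.3]), peaks)
        assert phi[0] == pytest.approx(2 * np.pi * 0.3 / 1.2)  # == pi/2

    def test_matches_bruteforce_per_interval_oracle(self, rng):
        peaks = PeakTrain(np.sort(rng.uniform(0, 60, 50)))
        t = rng.uniform(peaks.peak_times[0], peaks.peak_times[-1], 200)
        expected = np.empty_like(t)
        p = peaks.peak_times
        for i, ti in enumerate(t):  # brute force: scan intervals
            for k in range(p.size - 1):
                if p[k] <= ti < p[k + 1]:
                    expected[i] = 2 * np.pi * (ti - p[k]) / (p[k + 1] - p[k])
                    break
        assert np.allclose(cardiac_phase_at(t, peaks), expected)

    def test_piecewise_linear_slope(self):
        peaks = PeakTrain(np.array([0.0, 0.8, 1.6]))
        t = np.linspace(0.0, 0.79, 40)
        phi = cardiac_phase_at(t, peaks)
        slopes = np.diff(phi) / np.diff(t)
        assert np.allclose(slopes, 2 * np.pi / 0.8)

    def test_extrapolation_uses_nearest_interval(self):
        peaks = PeakTrain(np.array([1.0, 2.0, 4.0]))
        # before first peak: interval length 1.0
        assert cardiac_phase_at(np.array([0.5]), peaks)[0] == pytest.approx(np.pi)
        # after last peak: interval length 2.0
        assert cardiac_phase_at(np.array([5.0]), peaks)[0] == pytest.approx(np.pi)

    def test_range_and_insufficient_peaks(self):
        with pytest.raises(PeakDetectionError):
            cardiac_phase_at(np.array([0.0]), PeakTrain(np.array([1.0])))
        peaks = PeakTrain(np.array([0.0, 1.1, 2.3, 3.1]))
        phi = cardiac_phase_at(np.linspace(-1, 5, 300), peaks)
        assert np.all((phi >= 0) & (phi < 2 * np.pi))


class TestRespiratoryPhase:
    def test_range_and_sign_convention(self):
        rec = sinusoid_recording()
        t = np.linspace(5, 55, 400)
        phi = respiratory_phase_at(t, rec)
        assert np.all(np.abs(phi) <= np.pi + 1e-12)
        # inspiration (rising trace) → positive phase
        rising = np.interp(t + 0.2, rec.time, rec.respiratory) > np.interp(
            t - 0.2, rec.time, rec.respiratory
        )
        interior = np.abs(np.interp(t, rec.time, rec.respiratory)) < 0.9
        assert np.all(phi[rising & interior] > 0)
        assert np.all(phi[~rising & interior] < 0)

    def test_extremes_map_to_zero_and_pi(self):
        rec = sinusoid_recording(period=4.0)
        trough_t = np.array([3.0, 7.0, 11.0])  # sin minima
        peak_t = np.array([1.0, 5.0, 9.0])  # maxima during inspiration end
        assert np.all(np.abs(respiratory_phase_at(trough_t, rec)) < 0.3)
        assert np.all(np.abs(respiratory_phase_at(peak_t, rec)) > np.pi - 0.3)

    def test_median_amplitude_during_expiration_is_minus_half_pi(self):
        rec = sinusoid_recording(period=4.0)
        # R = sin(2πt/4) crosses its median (0) going down at t = 2 mod 4
        phi = respiratory_phase_at(np.array([6.0, 10.0]), rec)
        assert np.allclose(phi, -np.pi / 2, atol=0.15)

    def test_scale_and_offset_invariance(self):
        rec = sinusoid_recording()
        scaled = PhysioRecording(
            rec.sampling_rate, rec.time, rec.cardiac, 7.5 * rec.respiratory + 3.0
        )
        t = np.linspace(5, 55, 200)
        # equalization is invariant up to histogram-bin resolution (π/n_bins)
        assert np.allclose(
            respiratory_phase_at(t, rec),
            respiratory_phase_at(t, scaled),
            atol=np.pi / 100 + 1e-9,
        )

    def test_constant_trace_is_degenerate(self):
        rec = sinusoid_recording()
        flat = PhysioRecording(rec.sampling_rate, rec.time, rec.cardiac,
                               np.ones_like(rec.time))
        with pytest.raises(DegenerateSignalError):
            respiratory_phase_at(np.array([1.0]), flat)


class TestHeartRate:
    @pytest.mark.parametrize("interval,bpm", [(1.0, 60.0), (0.8, 75.0)])
    def test_constant_rate(self, interval, bpm):
        peaks = PeakTrain(np.arange(0, 60, interval))
        hr = heart_rate_series(peaks, np.linspace(5, 50, 20), window=6.0)
        assert np.allclose(hr, bpm)

    def test_alternating_intervals_match_bruteforce_window(self):
        intervals = np.tile([0.8, 1.0], 30)
        peaks = PeakTrain(np.concatenate([[0.0], np.cumsum(intervals)]))
        times = np.linspace(5, 45, 37)
        window = 6.0
        hr = heart_rate_series(peaks, times, window=window)
        p = peaks.peak_times
        for ti, got in zip(times, hr):
            covered = [
                p[k + 1] - p[k]
                for k in range(p.size - 1)
                if p[k] < ti + window / 2 and p[k + 1] > ti - window / 2
            ]
            assert got == pytest.approx(60.0 / np.mean(covered))

    def test_offset_invariance_of_trace_does_not_affect_hr(self):
        # HR depends only on peak times, which an offset does not move
        peaks = PeakTrain(np.arange(0, 30, 0.9))
        t = np.linspace(2, 28, 10)
        assert np.allclose(heart_rate_series(peaks, t), 60 / 0.9)


class TestRVT:
    def test_sinusoid_gives_2a_over_t(self):
        A, T = 2.5, 4.0
        rec = sinusoid_recording(duration=80.0, period=T, amplitude=A)
        t = np.linspace(15, 65, 30)
        rvt = rvt_series(rec, t)
        assert np.allclose(rvt, 2 * A / T, rtol=0.05)

    def test_constant_trace_is_degenerate(self):
        rec = sinusoid_recording()
        flat = PhysioRecording(rec.sampling_rate, rec.time, rec.cardiac,
                               np.zeros_like(rec.time))
        with pytest.raises(DegenerateSignalError):
            rvt_series(flat, np.array([10.0]))

    def test_amplitude_modulated_breathing_matches_per_breath_table(self):
        fs, T = 50.0, 4.0
        t = np.arange(int(60 * fs)) / fs
        depths = 1.0 + 0.4 * np.sin(2 * np.pi * t / 30.0)  # slow depth drift
        resp = depths * np.sin(2 * np.pi * t / T)
        rec = PhysioRecording(fs, t, np.cos(t), resp)
        # per-breath oracle: peaks near T/4 + kT, troughs near 3T/4 + kT;
        # query the midpoint of breath k, where the interpolant hits the
        # breath's own value exactly
        k = 7
        peak_t = T / 4 + k * T  # 29.0
        next_peak_t = peak_t + T  # 33.0
        trough_t = peak_t - T / 2  # 27.0
        rvt = rvt_series(rec, np.array([(peak_t + next_peak_t) / 2]))
        depth = resp[int(peak_t * fs)] - resp[int(trough_t * fs)]
        assert rvt[0] == pytest.approx(depth / T, rel=0.1)

    def test_offset_invariance(self):
        A, T = 1.5, 4.0
        rec = sinusoid_recording(duration=60.0, period=T, amplitude=A)
        shifted = PhysioRecording(rec.sampling_rate, rec.time, rec.cardiac,
                                  rec.respiratory + 10.0)
        t = np.linspace(10, 50, 15)
        assert np.allclose(rvt_series(rec, t), rvt_series(shifted, t), rtol=1e-6)
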