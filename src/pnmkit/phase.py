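"""Cardiac/respiratory phase assignment and slow physiological rate series.

Cardiac phase advances linearly from 0 to 2π between successive pulse peaks.
Respiratory phase follows the amplitude-histogram (equalization) convention:
the bellows amplitude is ranked against the run's amplitude distribution and
signed by the derivative, so inspiration maps to (0, +π] and expiration to
[−π, 0) — both the timing and the depth of breathing enter the phase.

Heart rate (HR) and respiration volume per time (RVT) are slowly varying
confound series evaluated at the same per-slice acquisition times. No
cardiac/respiratory response-function convolution is applied; the raw
interpolated series are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, PeakDetectionError
from .io import PeakTrain, PhysioRecording, SliceTiming, _moving_average, detect_cardiac_peaks


@dataclass
class PhaseSeries:
    """Cardiac and respiratory phase at every (volume, slice) sample."""

    cardiac: np.ndarray  # radians in [0, 2π), shape (n_volumes, n_slices)
    respiratory: np.ndarray  # radians in [−π, π], same shape

    def __post_init__(self) -> None:
        if self.cardiac.shape != self.respiratory.shape:
            raise ValueError("cardiac and respiratory phase shapes differ")


@dataclass
class RateSeries:
    """Heart rate (bpm) and RVT (bellows units / s) at each (volume, slice)."""

    hr: np.ndarray
    rvt: np.ndarray


def cardiac_phase_at(times: np.ndarray, peaks: PeakTrain) -> np.ndarray:
    """Phase in [0, 2π): linear ramp between consecutive pulse peaks.

    For t between peaks p_k and p_{k+1}:  φ = 2π (t − p_k)/(p_{k+1} − p_k).
    Times before the first / after the last peak extrapolate with the nearest
    interval length (phase wraps modulo 2π).
    """
    p = peaks.peak_times
    if p.size < 2:
        raise PeakDetectionError("cardiac phase requires at least 2 peaks")
    t = np.asarray(times, dtype=float)
    shape = t.shape
    t = t.ravel()
    intervals = np.diff(p)
    # interval index for each time; clip so outside times reuse edge intervals
    k = np.clip(np.searchsorted(p, t, side="right") - 1, 0, intervals.size - 1)
    frac = (t - p[k]) / intervals[k]
    phase = 2 * np.pi * np.mod(frac, 1.0)
    # guard the half-open upper bound against float rounding
    phase[phase >= 2 * np.pi] = 0.0
    return phase.reshape(shape)


def _signed_amplitude_rank(
    trace: np.ndarray,
    sampling_rate: float,
    n_bins: int,
    smoothing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (F, sign): histogram-equalized rank and derivative sign."""
    finite = trace[np.isfinite(trace)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise DegenerateSignalError(
            "respiratory trace is constant; amplitude histogram is degenerate"
        )
    hist, edges = np.histogram(finite, bins=n_bins)
    cum = np.cumsum(hist) / finite.size
    idx = np.clip(np.digitize(trace, edges[1:-1]), 0, n_bins - 1)
    rank = cum[idx]

    width = max(1, int(round(smoothing * sampling_rate)))
    smooth = _moving_average(np.nan_to_num(trace, nan=np.nanmean(finite)), width)
    deriv = np.gradient(smooth)
    # relative dead-band: |dR/dt| this small is "zero" regardless of trace
    # scaling, so the sign (and hence the phase) is scale-invariant
    tiny = 1e-8 * np.max(np.abs(deriv)) if deriv.size else 0.0
    sign = np.where(np.abs(deriv) > tiny, np.sign(deriv), 0.0)
    # zero-derivative samples (breath extremes) inherit the previous sign to
    # avoid sign chatter; leading zeros take the first nonzero sign
    nz = sign != 0
    if nz.any():
        first = sign[nz][0]
        out = np.empty_like(sign)
        last = first
        for i, s in enumerate(sign):
            if s != 0:
                last = s
            out[i] = last
        sign = out
    else:
        sign = np.ones_like(sign)
    return rank, sign


def respiratory_phase_at(
    times: np.ndarray,
    recording: PhysioRecording,
    n_bins: int = 100,
    smoothing: float = 0.5,
) -> np.ndarray:
    """Signed histogram-equalized respiratory phase in [−π, π].

    φ(t) = sign(dR/dt) · π · F(R(t)), where F is the normalized cumulative
    amplitude histogram of the whole run (so φ is invariant to affine
    rescaling of the bellows trace) and the sign separates inspiration (+)
    from expiration (−).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    rank, sign = _signed_amplitude_rank(
        recording.respiratory, recording.sampling_rate, n_bins, smoothing
    )
    t = np.asarray(times, dtype=float)
    shape = t.shape
    rank_t = np.interp(t.ravel(), recording.time, rank)
    sign_t = np.sign(np.interp(t.ravel(), recording.time, sign))
    sign_t[sign_t == 0] = 1.0
    return (sign_t * np.pi * rank_t).reshape(shape)


def heart_rate_series(
    peaks: PeakTrain,
    times: np.ndarray,
    window: float = 6.0,
) -> np.ndarray:
    """Windowed heart rate in beats per minute at each requested time.

    HR(t) = 60 / mean(inter-peak intervals overlapping the ``window``-second
    window centered at t). A window covering no interval is filled from the
    nearest defined time.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    p = peaks.peak_times
    if p.size < 2:
        raise PeakDetectionError("heart rate requires at least 2 peaks")
    starts, ends = p[:-1], p[1:]
    lengths = ends - starts
    t = np.asarray(times, dtype=float)
    shape = t.shape
    flat = t.ravel()
    hr = np.full(flat.size, np.nan)
    half = window / 2.0
    for i, ti in enumerate(flat):
        overlap = (starts < ti + half) & (ends > ti - half)
        if overlap.any():
            hr[i] = 60.0 / lengths[overlap].mean()
    if np.isnan(hr).any():
        defined = np.where(~np.isnan(hr))[0]
        if defined.size == 0:
            raise PeakDetectionError("no window overlaps any inter-peak interval")
        missing = np.where(np.isnan(hr))[0]
        nearest = defined[np.argmin(np.abs(flat[missing][:, None] - flat[defined][None, :]), axis=1)]
        hr[missing] = hr[nearest]
    return hr.reshape(shape)


def _breath_extrema(
    recording: PhysioRecording,
    min_breath_interval: float,
    smoothing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(peak times, trough times) of the bellows trace."""
    peaks = detect_cardiac_peaks(
        recording,
        min_interval=min_breath_interval,
        smoothing_width=smoothing,
        channel="respiratory",
    ).peak_times
    neg = PhysioRecording(
        sampling_rate=recording.sampling_rate,
        time=recording.time,
        cardiac=recording.cardiac,
        respiratory=-recording.respiratory,
        triggers=recording.triggers,
    )
    troughs = detect_cardiac_peaks(
        neg,
        min_interval=min_breath_interval,
        smoothing_width=smoothing,
        channel="respiratory",
    ).peak_times
    return peaks, troughs


def rvt_series(
    recording: PhysioRecording,
    times: np.ndarray,
    min_breath_interval: float = 2.0,
    smoothing: float = 0.5,
) -> np.ndarray:
    """Respiration volume per time at each requested time.

    Per breath: (end-inspiration peak amplitude − preceding trough amplitude)
    divided by the time to the next peak. Breath-wise values are placed at
    breath midpoints and linearly interpolated (edges held constant).
    """
    try:
        peaks, troughs = _breath_extrema(recording, min_breath_interval, smoothing)
    except (DegenerateSignalError, PeakDetectionError) as exc:
        raise DegenerateSignalError(
            f"breathing cycle undetectable: {exc}"
        ) from exc
    if peaks.size < 2:
        raise DegenerateSignalError("breathing cycle undetectable: <2 breaths")
    amp = recording.respiratory
    t = recording.time
    values, midpoints = [], []
    for k in range(peaks.size - 1):
        pk, pk1 = peaks[k], peaks[k + 1]
        prev = troughs[troughs < pk]
        if prev.size == 0:
            continue
        trough = prev[-1]
        depth = np.interp(pk, t, amp) - np.interp(trough, t, amp)
        period = pk1 - pk
        values.append(max(depth, 0.0) / period)
        midpoints.append(0.5 * (pk + pk1))
    if not values:
        raise DegenerateSignalError("no complete breath (trough→peak→peak) found")
    q = np.asarray(times, dtype=float)
    return np.interp(q.ravel(), np.asarray(midpoints), np.asarray(values)).reshape(q.shape)


def compute_phase_series(
    recording: PhysioRecording,
    timing: SliceTiming,
    cardiac_peaks: PeakTrain | None = None,
    n_bins: int = 100,
) -> PhaseSeries:
    """Assign cardiac and respiratory phase to every (volume, slice) time.

    Simultaneously acquired slices (identical slice times, e.g. multiband)
    receive identical phases.
    """
    if cardiac_peaks is None:
        cardiac_peaks = detect_cardiac_peaks(recording)
    return PhaseSeries(
        cardiac=cardiac_phase_at(timing.slice_times, cardiac_peaks),
        respiratory=respiratory_phase_at(timing.slice_times, recording, n_bins=n_bins),
    )


def compute_rate_series(
    recording: PhysioRecording,
    timing: SliceTiming,
    cardiac_peaks: PeakTrain | None = None,
    hr_window: float = 6.0,
) -> RateSeries:
    """Heart-rate and RVT confound series at every (volume, slice) time."""
    if cardiac_peaks is None:
        cardiac_peaks = detect_cardiac_peaks(recording)
    return RateSeries(
        hr=heart_rate_series(cardiac_peaks, timing.slice_times, window=hr_window),
        rvt=rvt_series(recording, timing.slice_times),
    )
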