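"""Physiological log parsing, cardiac peak detection and slice timing.

A physiological recording is a set of uniformly sampled channels (pulse
oximeter, respiratory bellows) logged on one clock together with scanner
volume triggers, typically at 50 Hz. All times inside the package are seconds
relative to the first physiological sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    DegenerateSignalError,
    FormatError,
    PeakDetectionError,
    TimingError,
)

SLICE_ORDERS = ("ascending", "descending", "interleaved")

#: default column layout of a 4-column physio log
DEFAULT_COLUMNS: Mapping[str, int] = {
    "time": 0,
    "cardiac": 1,
    "respiratory": 2,
    "trigger": 3,
}


@dataclass
class PhysioRecording:
    """Uniformly sampled cardiac/respiratory traces plus volume triggers.

    Parameters
    ----------
    sampling_rate : float
        Samples per second of the logging device (Hz).
    time : ndarray
        Sample times in seconds, strictly increasing with constant step
        ``1/sampling_rate``, starting at 0.
    cardiac : ndarray
        Pulse-oximeter waveform, arbitrary units.
    respiratory : ndarray
        Bellows amplitude R(t), arbitrary units.
    triggers : ndarray
        Volume-onset event times in seconds, within the sampled span.
    """

    sampling_rate: float
    time: np.ndarray
    cardiac: np.ndarray
    respiratory: np.ndarray
    triggers: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.respiratory = np.asarray(self.respiratory, dtype=float)
        self.triggers = np.asarray(self.triggers, dtype=float)
        if self.sampling_rate <= 0:
            raise TimingError("sampling_rate must be positive")
        n = self.time.size
        if self.cardiac.size != n or self.respiratory.size != n:
            raise FormatError(
                "cardiac and respiratory traces must match the time vector "
                f"(got {self.cardiac.size}, {self.respiratory.size} vs {n})"
            )
        if n >= 2:
            dt = np.diff(self.time)
            expected = 1.0 / self.sampling_rate
            if np.any(dt <= 0) or np.max(np.abs(dt - expected)) > 0.01 * expected:
                raise TimingError(
                    "time vector is not uniform at the declared sampling rate"
                )
        if self.triggers.size and n:
            lo, hi = self.time[0], self.time[-1]
            if self.triggers.min() < lo - 1e-9 or self.triggers.max() > hi + 1e-9:
                raise TimingError("trigger times fall outside the sampled span")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0


@dataclass
class PeakTrain:
    """Strictly increasing event times of a detected physiological cycle."""

    peak_times: np.ndarray
    source: str = "cardiac"

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size >= 2 and np.any(np.diff(self.peak_times) <= 0):
            raise PeakDetectionError("peak times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.peak_times)


@dataclass
class SliceTiming:
    """Acquisition time of every (volume, slice) pair.

    ``slice_times[v, s]`` is the absolute acquisition time (s) of slice ``s``
    in volume ``v``; each lies in ``[trigger[v], trigger[v] + tr)``.
    """

    tr: float
    n_slices: int
    n_volumes: int
    order: str
    slice_times: np.ndarray
    triggers: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.slice_times = np.asarray(self.slice_times, dtype=float)
        if self.order not in SLICE_ORDERS:
            raise FormatError(f"unknown slice order {self.order!r}")
        if self.slice_times.shape != (self.n_volumes, self.n_slices):
            raise FormatError("slice_times shape must be (n_volumes, n_slices)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tr": self.tr,
            "n_slices": self.n_slices,
            "order": self.order,
            "triggers": np.asarray(self.triggers, dtype=float).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SliceTiming":
        payload = json.loads(Path(path).read_text())
        return extract_slice_times(
            np.asarray(payload["triggers"], dtype=float),
            tr=payload["tr"],
            n_slices=payload["n_slices"],
            order=payload["order"],
        )


def slice_offsets(tr: float, n_slices: int, order: str) -> np.ndarray:
    """Within-volume acquisition offset of each slice, in slice index order.

    Slices are spaced uniformly at ``tr / n_slices``. The interleaved
    convention is odd-numbered slices (1-based: 1, 3, 5, ...) acquired first,
    then even-numbered — vendor conventions differ, so this is explicit and
    ``order`` is always user-supplied.
    """
    if order not in SLICE_ORDERS:
        raise FormatError(f"unknown slice order {order!r}")
    dt = tr / n_slices
    if order == "ascending":
        sequence = np.arange(n_slices)
    elif order == "descending":
        sequence = np.arange(n_slices)[::-1]
    else:  # interleaved: 0-based even indices (1-based odd) first
        sequence = np.concatenate(
            [np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)]
        )
    offsets = np.empty(n_slices)
    offsets[sequence] = np.arange(n_slices) * dt
    return offsets


def extract_slice_times(
    triggers: Sequence[float],
    tr: float,
    n_slices: int,
    order: str = "ascending",
    rel_tol: float = 0.05,
) -> SliceTiming:
    """Expand volume triggers into per-(volume, slice) acquisition times.

    Parameters
    ----------
    triggers : array-like
        Volume onset times (s); must be approximately ``tr`` apart.
    rel_tol : float
        Allowed relative deviation of inter-trigger spacing from ``tr``.
    """
    triggers = np.asarray(triggers, dtype=float)
    if triggers.size < 1:
        raise TimingError("at least one volume trigger is required")
    if triggers.size >= 2:
        gaps = np.diff(triggers)
        bad = np.where(np.abs(gaps - tr) > rel_tol * tr)[0]
        if bad.size:
            i = int(bad[0])
            raise TimingError(
                f"trigger interval {i} is {gaps[i]:.4f} s, expected ~{tr:.4f} s"
            )
    offsets = slice_offsets(tr, n_slices, order)
    slice_times = triggers[:, None] + offsets[None, :]
    return SliceTiming(
        tr=tr,
        n_slices=n_slices,
        n_volumes=triggers.size,
        order=order,
        slice_times=slice_times,
        triggers=triggers,
    )


def _moving_average(x: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return x
    kernel = np.ones(width_samples) / width_samples
    pad = width_samples // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + x.size]
    return out


def detect_cardiac_peaks(
    recording: PhysioRecording,
    min_interval: float = 0.4,
    smoothing_width: float = 0.1,
    channel: str = "cardiac",
) -> PeakTrain:
    """Locate pulse peaks in the cardiac (or respiratory) trace.

    The trace is smoothed with a moving average of ``smoothing_width``
    seconds, then local maxima separated by at least ``min_interval`` seconds
    (a refractory period; the 0.4 s default corresponds to a 150 bpm ceiling)
    are returned at their sample times.
    """
    if min_interval <= 0:
        raise PeakDetectionError("min_interval must be positive")
    trace = getattr(recording, channel)
    finite = np.isfinite(trace)
    if not finite.any() or np.nanstd(trace) == 0:
        raise DegenerateSignalError(f"{channel} trace is constant or all-NaN")
    x = np.where(finite, trace, np.nanmean(trace))
    width = max(1, int(round(smoothing_width * recording.sampling_rate)))
    smooth = _moving_average(x, width)
    distance = max(1, int(round(min_interval * recording.sampling_rate)))
    idx, _ = find_peaks(smooth, distance=distance)
    if idx.size < 2:
        raise PeakDetectionError(
            f"found only {idx.size} peak(s); at least 2 are required"
        )
    return PeakTrain(peak_times=recording.time[idx], source=channel)


def read_physio_log(
    path: str | Path,
    column_spec: Mapping[str, int | str] | None = None,
    sampling_rate: float = 50.0,
    trigger_threshold: float | None = None,
    delimiter: str | None = None,
) -> PhysioRecording:
    """Read a delimited physio log into a validated :class:`PhysioRecording`.

    Parameters
    ----------
    path : path
        TSV/CSV file, one row per sample; header optional.
    column_spec : mapping
        Maps channel names (``time``, ``cardiac``, ``respiratory``,
        ``trigger``) to 0-based column indices or header names. ``time`` and
        ``trigger`` are optional: without ``time`` the clock is reconstructed
        from ``sampling_rate``; without ``trigger`` the recording carries no
        events.
    trigger_threshold : float, optional
        Level whose upward crossings in the trigger channel mark volume
        onsets. Defaults to the channel's mid-range.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"physio log not found: {path}")
    spec = dict(column_spec) if column_spec is not None else dict(DEFAULT_COLUMNS)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else r"\s+"
    by_name = any(isinstance(v, str) for v in spec.values())
    if by_name:
        header = 0
    else:
        # positional columns: sniff whether the first row is a header line
        with open(path) as fh:
            first = fh.readline()
        tokens = first.replace(",", " ").split()
        try:
            [float(tok) for tok in tokens]
            header = None
        except ValueError:
            header = 0
    df = pd.read_csv(path, sep=delimiter, header=header, comment="#")

    def column(name: str) -> np.ndarray:
        key = spec[name]
        try:
            series = df[key] if isinstance(key, str) else df.iloc[:, key]
        except (KeyError, IndexError):
            raise FormatError(
                f"declared column {key!r} for channel {name!r} not present in {path.name}"
            ) from None
        return np.asarray(series, dtype=float)

    for required in ("cardiac", "respiratory"):
        if required not in spec:
            raise FormatError(f"column_spec must declare a {required!r} channel")

    cardiac = column("cardiac")
    respiratory = column("respiratory")
    n = cardiac.size
    if "time" in spec:
        time = column("time")
        time = time - time[0]
        dt = np.diff(time)
        expected = 1.0 / sampling_rate
        if dt.size and (np.any(dt <= 0) or np.max(np.abs(dt - expected)) > 0.01 * expected):
            raise TimingError(
                f"time column of {path.name} is not uniform at {sampling_rate} Hz"
            )
        # snap to the exact grid to avoid float drift from text round-trips
        time = np.arange(n) / sampling_rate
    else:
        time = np.arange(n) / sampling_rate

    triggers = np.empty(0)
    if "trigger" in spec:
        trig = column("trigger")
        if trigger_threshold is None:
            trigger_threshold = 0.5 * (np.nanmin(trig) + np.nanmax(trig))
        above = trig > trigger_threshold
        onsets = np.where(~above[:-1] & above[1:])[0] + 1
        if above[0]:
            onsets = np.concatenate([[0], onsets])
        triggers = time[onsets]

    return PhysioRecording(
        sampling_rate=sampling_rate,
        time=time,
        cardiac=cardiac,
        respiratory=respiratory,
        triggers=triggers,
    )


def write_physio_log(recording: PhysioRecording, path: str | Path) -> None:
    """Write a recording as a 4-column TSV (time, cardiac, resp, trigger).

    The trigger channel is a 0/1 pulse that rises at each trigger sample, so
    ``read_physio_log`` round-trips the event times to sample precision.
    """
    trig = np.zeros(recording.time.size)
    if recording.triggers.size:
        idx = np.searchsorted(recording.time, recording.triggers - 1e-9)
        idx = np.clip(idx, 0, trig.size - 1)
        trig[idx] = 1.0
    df = pd.DataFrame(
        {
            "time": recording.time,
            "cardiac": recording.cardiac,
            "respiratory": recording.respiratory,
            "trigger": trig,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
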