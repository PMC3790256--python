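"""Seeded synthetic physiological traces and matched 4D fMRI data.

The generator emulates a resting multi-slice EPI run with independent
physiological monitoring: a quasi-periodic pulse-oximeter waveform (~1.1 Hz,
raised-cosine systolic peak per beat), a bellows trace (~0.25 Hz) with
per-breath period and depth jitter, volume triggers on the same 50 Hz clock,
and image voxels carrying baseline, cardiac/respiratory Fourier components
locked to each voxel's true slice time (so long-TR sampling aliases them), a
cardio-respiratory interaction sideband, linear drift and Gaussian thermal
noise. Every quantity needed to verify recovery — beat times, breath depths,
per-voxel injected amplitudes, the noise-voxel mask — is returned as ground
truth.

The noise model is additive (real physiological noise is partly
multiplicative); amplitudes are in image units on a baseline of 100, i.e.
cardiac_amp=2.0 is a 2% signal fluctuation, at the strong end of what
pulsatile brainstem/CSF-boundary voxels show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .errors import PnmError
from .io import PeakTrain, PhysioRecording, SliceTiming, extract_slice_times
from .phase import cardiac_phase_at


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the synthetic resting run.

    Defaults mirror a 3 T resting demonstration at desk scale: TR 3 s,
    100 volumes, 50 Hz physiological logging, heart ~66 bpm, breathing
    ~0.25 Hz, 16×16×8 voxel grid with half the voxels carrying injected
    physiological noise.
    """

    duration: float | None = None  # s; default n_volumes·tr + 4
    physio_rate: float = 50.0  # Hz
    hr_mean: float = 66.0  # bpm
    hr_sd: float = 3.0  # bpm, beat-to-beat variability
    resp_period_mean: float = 4.0  # s
    resp_period_sd: float = 0.4  # s
    breath_depth_sd: float = 0.15  # fractional depth jitter
    tr: float = 3.0  # s
    n_slices: int = 8
    n_volumes: int = 100
    nx: int = 16
    ny: int = 16
    slice_order: str = "interleaved"
    baseline: float = 100.0  # image units
    cardiac_amp: float = 2.0  # fundamental amplitude, image units
    resp_amp: float = 2.0
    interaction_amp: float = 0.8
    thermal_sd: float = 1.0
    drift_amp: float = 1.0
    noise_voxel_fraction: float = 0.5
    trigger_start: float = 1.0  # s, first volume onset
    seed: int = 42

    def __post_init__(self) -> None:
        if self.physio_rate <= 0 or self.tr <= 0 or self.hr_mean <= 0:
            raise PnmError("rates and durations must be positive")
        if not 0 <= self.noise_voxel_fraction <= 1:
            raise PnmError("noise_voxel_fraction must be in [0, 1]")

    @property
    def total_duration(self) -> float:
        return (
            self.duration
            if self.duration is not None
            else self.n_volumes * self.tr + 4.0
        )


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analysis must recover."""

    beat_times: np.ndarray
    breath_trough_times: np.ndarray  # breath boundaries (bellows minima)
    breath_peak_times: np.ndarray  # end-inspiration maxima
    breath_periods: np.ndarray
    breath_depths: np.ndarray
    f_cardiac: float  # mean cardiac frequency, Hz
    f_resp: float  # mean respiratory frequency, Hz
    noise_mask: np.ndarray | None = None
    cardiac_amp_map: np.ndarray | None = None  # order-1 amplitude per voxel
    resp_amp_map: np.ndarray | None = None
    interaction_amp_map: np.ndarray | None = None

    def cardiac_phase(self, times: np.ndarray) -> np.ndarray:
        """True cardiac phase (0..2π) from the exact beat times."""
        return cardiac_phase_at(times, PeakTrain(self.beat_times))

    def resp_cycle_phase(self, times: np.ndarray) -> np.ndarray:
        """True within-breath phase ψ in [0, 2π), trough-to-trough."""
        b = self.breath_trough_times
        t = np.asarray(times, dtype=float)
        shape = t.shape
        t = t.ravel()
        periods = np.diff(b)
        k = np.clip(np.searchsorted(b, t, side="right") - 1, 0, periods.size - 1)
        u = np.mod((t - b[k]) / periods[k], 1.0)
        return (2 * np.pi * u).reshape(shape)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beat_times": self.beat_times.tolist(),
            "breath_trough_times": self.breath_trough_times.tolist(),
            "breath_peak_times": self.breath_peak_times.tolist(),
            "breath_periods": self.breath_periods.tolist(),
            "breath_depths": self.breath_depths.tolist(),
            "f_cardiac": self.f_cardiac,
            "f_resp": self.f_resp,
        }
        if self.noise_mask is not None:
            payload["noise_mask"] = self.noise_mask.astype(int).tolist()
        Path(path).write_text(json.dumps(payload))


def _event_times(
    rng: np.random.Generator,
    start: float,
    stop: float,
    mean_interval: float,
    sd_interval: float,
    min_interval: float,
) -> np.ndarray:
    times = [start]
    while times[-1] < stop:
        step = mean_interval + sd_interval * rng.standard_normal()
        times.append(times[-1] + max(step, min_interval))
    return np.asarray(times)


def simulate_physio_traces(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[PhysioRecording, GroundTruth]:
    """Generate the 50 Hz physiological log and its ground truth.

    The cardiac trace is a raised-cosine systolic bump (width 0.5 s) at each
    beat, so the waveform maximum falls exactly on the beat time. The bellows
    trace rises and falls as a raised cosine within each breath, scaled by
    that breath's depth. Volume triggers fire every TR.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    total = params.total_duration
    if total < 2 * params.resp_period_mean:
        raise PnmError("duration must cover at least two breaths")
    n = int(round(total * params.physio_rate))
    time = np.arange(n) / params.physio_rate

    # --- beats: intervals from jittered instantaneous heart rate
    base = 60.0 / params.hr_mean
    sd = base * (params.hr_sd / params.hr_mean)
    beats = _event_times(rng, 0.25, total, base, sd, 0.3)
    beats = beats[beats < total]

    cardiac = np.zeros(n)
    half_width = 0.25
    for bt in beats:
        lo = max(0, int(np.ceil((bt - half_width) * params.physio_rate)))
        hi = min(n, int(np.floor((bt + half_width) * params.physio_rate)) + 1)
        tt = time[lo:hi]
        cardiac[lo:hi] += 0.5 * (1 + np.cos(np.pi * (tt - bt) / half_width))

    # --- breaths: boundary (trough) times with jittered periods and depths
    troughs = _event_times(
        rng, 0.0, total, params.resp_period_mean, params.resp_period_sd, 1.5
    )
    periods = np.diff(troughs)
    depths = np.maximum(
        1.0 + params.breath_depth_sd * rng.standard_normal(periods.size), 0.2
    )
    respiratory = np.zeros(n)
    for k in range(periods.size):
        lo = int(np.ceil(troughs[k] * params.physio_rate))
        hi = min(n, int(np.ceil(troughs[k + 1] * params.physio_rate)))
        u = (time[lo:hi] - troughs[k]) / periods[k]
        respiratory[lo:hi] = depths[k] * 0.5 * (1 - np.cos(2 * np.pi * u))

    triggers = params.trigger_start + params.tr * np.arange(params.n_volumes)
    if triggers[-1] + params.tr > total:
        raise PnmError(
            "duration too short for the requested volume count"
        )

    recording = PhysioRecording(
        sampling_rate=params.physio_rate,
        time=time,
        cardiac=cardiac,
        respiratory=respiratory,
        triggers=triggers,
    )
    truth = GroundTruth(
        beat_times=beats,
        breath_trough_times=troughs,
        breath_peak_times=troughs[:-1] + periods / 2.0,
        breath_periods=periods,
        breath_depths=depths,
        f_cardiac=1.0 / np.diff(beats).mean(),
        f_resp=1.0 / periods.mean(),
    )
    return recording, truth


def default_slice_timing(params: SimulationParams) -> SliceTiming:
    """Slice timing implied by the simulation parameters."""
    triggers = params.trigger_start + params.tr * np.arange(params.n_volumes)
    return extract_slice_times(
        triggers, tr=params.tr, n_slices=params.n_slices, order=params.slice_order
    )


def _phase_locked(
    amp: np.ndarray, m_phase: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """amp·sin(phase + theta) for per-voxel theta: (nx,ny)⊗(nt,) → (nx,ny,nt)."""
    return amp[..., None] * (
        np.cos(theta)[..., None] * np.sin(m_phase)[None, None, :]
        + np.sin(theta)[..., None] * np.cos(m_phase)[None, None, :]
    )


def simulate_fmri(
    params: SimulationParams,
    truth: GroundTruth,
    timing: SliceTiming | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate the 4D series with injected, slice-time-locked noise.

    In noise voxels the signal is

        baseline + Σ_{m=1,2} A_m sin(m·φc + θ) + Σ_{m=1,2} B_m sin(m·ψ + θ')
                 + C sin(φc + ξ)·sin(ψ + ξ') + drift + N(0, thermal_sd²)

    with φc/ψ the true cardiac/breath phases at that voxel's slice time,
    A = (cardiac_amp, cardiac_amp/2), B likewise from resp_amp, C =
    interaction_amp, and per-voxel random phase offsets θ, θ', ξ, ξ'. The
    interaction is multiplicative (cardiac amplitude modulated by the breath
    cycle), so its spectrum carries both f_c ± f_r sidebands. Updates
    ``truth`` in place with the noise mask and injected amplitude maps and
    returns ``(data, noise_mask)``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if timing is None:
        timing = default_slice_timing(params)
    if timing.n_volumes != params.n_volumes or timing.n_slices != params.n_slices:
        raise PnmError("slice timing inconsistent with simulation parameters")
    nx, ny, nz, nt = params.nx, params.ny, params.n_slices, params.n_volumes

    noise_mask = rng.random((nx, ny, nz)) < params.noise_voxel_fraction
    data = np.full((nx, ny, nz, nt), params.baseline)
    slopes = params.drift_amp * rng.uniform(-1.0, 1.0, size=(nx, ny, nz))
    t_end = timing.slice_times.max()

    amp_c = np.where(noise_mask, params.cardiac_amp, 0.0)
    amp_r = np.where(noise_mask, params.resp_amp, 0.0)
    amp_x = np.where(noise_mask, params.interaction_amp, 0.0)

    for s in range(nz):
        ts = timing.slice_times[:, s]
        phic = truth.cardiac_phase(ts)
        psi = truth.resp_cycle_phase(ts)
        sig = np.zeros((nx, ny, nt))
        for m, scale in ((1, 1.0), (2, 0.5)):
            theta = rng.uniform(0, 2 * np.pi, size=(nx, ny))
            sig += _phase_locked(scale * amp_c[:, :, s], m * phic, theta)
            theta = rng.uniform(0, 2 * np.pi, size=(nx, ny))
            sig += _phase_locked(scale * amp_r[:, :, s], m * psi, theta)
        xi = rng.uniform(0, 2 * np.pi, size=(nx, ny))
        xi2 = rng.uniform(0, 2 * np.pi, size=(nx, ny))
        sig += (
            amp_x[:, :, s, None]
            * np.sin(phic[None, None, :] + xi[:, :, None])
            * np.sin(psi[None, None, :] + xi2[:, :, None])
        )
        sig += slopes[:, :, s, None] * (ts / t_end - 0.5)[None, None, :]
        sig += rng.normal(0.0, params.thermal_sd, size=(nx, ny, nt))
        data[:, :, s, :] += sig

    truth.noise_mask = noise_mask
    truth.cardiac_amp_map = amp_c
    truth.resp_amp_map = amp_r
    truth.interaction_amp_map = amp_x
    return data, noise_mask


def simulate_run(
    params: SimulationParams | None = None,
) -> tuple[np.ndarray, PhysioRecording, SliceTiming, GroundTruth]:
    """One-call synthetic study: 4D data, physio log, slice timing, truth."""
    if params is None:
        params = SimulationParams()
    recording, truth = simulate_physio_traces(params)
    timing = default_slice_timing(params)
    data, _ = simulate_fmri(params, truth, timing)
    return data, recording, timing, truth


def dense_voxel_series(
    params: SimulationParams,
    truth: GroundTruth,
    sampling_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A noise-free physiological voxel signal on a dense time grid.

    Returns ``(times, signal)`` with signal = cardiac_amp·sin(φc) +
    resp_amp·sin(ψ) + interaction_amp·sin(φc)·sin(ψ), useful for spectral
    checks of harmonics, the f_c ± f_r sidebands and aliasing.
    """
    fs = sampling_rate if sampling_rate is not None else params.physio_rate
    times = np.arange(int(params.total_duration * fs)) / fs
    phic = truth.cardiac_phase(times)
    psi = truth.resp_cycle_phase(times)
    signal = (
        params.cardiac_amp * np.sin(phic)
        + params.resp_amp * np.sin(psi)
        + params.interaction_amp * np.sin(phic) * np.sin(psi)
    )
    return times, signal
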