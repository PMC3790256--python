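"""Closed-form calculators: aliasing limits, sidebands, field/voxel scaling.

Physiological noise amplitude scales with the square of the main field B0
while thermal-limited signal scales linearly with B0 and thermal SNR scales
linearly with voxel volume. The physiological-to-thermal noise ratio of an
acquisition therefore scales as B0² × V, which is what these calculators
chain across acquisition changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PnmError


def bpm_to_hz(bpm: float) -> float:
    """Convert beats (or breaths) per minute to Hz."""
    return bpm / 60.0


@dataclass(frozen=True)
class AcquisitionPoint:
    """A (field strength, voxel size[, TR]) operating point.

    Give either ``voxel_edge`` (mm, isotropic) or ``voxel_volume`` (mm³).
    """

    b0: float
    voxel_edge: float | None = None
    voxel_volume: float | None = None
    tr: float | None = None

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise PnmError("b0 must be positive")
        if self.voxel_edge is None and self.voxel_volume is None:
            raise PnmError("give voxel_edge or voxel_volume")
        if self.voxel_edge is not None and self.voxel_edge <= 0:
            raise PnmError("voxel_edge must be positive")
        if self.voxel_volume is not None and self.voxel_volume <= 0:
            raise PnmError("voxel_volume must be positive")
        if self.tr is not None and self.tr <= 0:
            raise PnmError("tr must be positive")

    @property
    def volume(self) -> float:
        """Voxel volume in mm³."""
        if self.voxel_volume is not None:
            return self.voxel_volume
        return float(self.voxel_edge) ** 3


def phys_thermal_ratio_factor(ref: AcquisitionPoint, new: AcquisitionPoint) -> float:
    """Change in physiological/thermal noise ratio between two acquisitions.

    (B0_new/B0_ref)² × (V_new/V_ref). At fixed 3 mm voxels, 3 T → 7 T gives
    (7/3)² ≈ 5.4; shrinking the 7 T voxel to 1 mm multiplies by 1/27, i.e.
    about five-fold *below* the 3 T/3 mm ratio.
    """
    return (new.b0 / ref.b0) ** 2 * (new.volume / ref.volume)


def matched_voxel_edge(ref: AcquisitionPoint, b0_new: float) -> float:
    """Isotropic voxel edge at ``b0_new`` that keeps the noise ratio fixed.

    Solves (b0_new/b0_ref)² × (V_new/V_ref) = 1 for the edge:
    edge = (V_ref × (b0_ref/b0_new)²)^(1/3). A 3 T/3 mm reference matched at
    7 T gives ≈ 1.7 mm.
    """
    if b0_new <= 0:
        raise PnmError("b0_new must be positive")
    return float((ref.volume * (ref.b0 / b0_new) ** 2) ** (1.0 / 3.0))


def max_tr_no_alias(f_max: float) -> float:
    """Longest TR that samples ``f_max`` (Hz) without aliasing: 1/(2·f_max).

    The volume sampling rate 1/TR must be at least twice the highest signal
    frequency (the cardiac fundamental for physiological noise); e.g. hearts
    up to 75 bpm (1.25 Hz) require TR < 0.4 s.
    """
    if f_max <= 0:
        raise PnmError("f_max must be positive")
    return 1.0 / (2.0 * f_max)


def aliased_frequency(f: float, tr: float) -> float:
    """Apparent frequency of an ``f`` Hz signal sampled every ``tr`` seconds.

    |f − round(f·TR)/TR|, folded into [0, 1/(2·TR)]. Frequencies below the
    Nyquist rate are unchanged.
    """
    if f <= 0 or tr <= 0:
        raise PnmError("f and tr must be positive")
    return abs(f - np.round(f * tr) / tr)


def interaction_sidebands(f_cardiac: float, f_resp: float) -> tuple[float, float]:
    """Sum/difference frequencies of cardio-respiratory coupling.

    Returns (f_cardiac − f_resp, f_cardiac + f_resp); e.g. 1.0 ± 0.3 Hz →
    (0.7, 1.3) Hz. Requires f_cardiac > f_resp > 0.
    """
    if not f_cardiac > f_resp > 0:
        raise PnmError("need f_cardiac > f_resp > 0")
    return (f_cardiac - f_resp, f_cardiac + f_resp)
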