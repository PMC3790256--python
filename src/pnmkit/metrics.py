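"""Temporal-SNR quality metrics before and after physiological cleanup.

tSNR is the voxel time-series mean divided by its temporal standard
deviation. After nuisance regression the temporal standard deviation is
normalized by the true degrees of freedom, sqrt(RSS/DOF), so that adding
regressors cannot improve the corrected tSNR "for free" — random regressors
soak up variance but also cost DOF, and the two cancel in expectation.

Undefined voxels (zero variance, zero mean, outside a mask) are NaN and are
excluded from all summaries.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError, DOFError, SummaryError


def tsnr_map(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    ddof: int = 1,
) -> np.ndarray:
    """Voxelwise temporal SNR: mean / sample standard deviation.

    ``ddof=1`` (sample std over N−1) by default. Zero-variance voxels are
    returned as NaN rather than infinity.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise DimensionError("data must be 4D (x, y, z, t)")
    if data.shape[-1] < 3:
        raise DimensionError("tSNR requires at least 3 time points")
    mean = data.mean(axis=-1)
    std = data.std(axis=-1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(std > 0, mean / std, np.nan)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != out.shape:
            raise DimensionError("mask shape does not match data")
        out = np.where(mask, out, np.nan)
    return out


def dof_corrected_tstd(residuals: np.ndarray, dof: int) -> np.ndarray:
    """Temporal standard deviation of residuals normalized by the true DOF.

    sqrt(RSS / DOF), with DOF = N − 1 − N_reg from the nuisance fit. Equals
    the ordinary sample std exactly when DOF = N − 1 and the residual mean
    is zero.
    """
    if dof < 1:
        raise DOFError(f"dof must be >= 1, got {dof}")
    residuals = np.asarray(residuals, dtype=float)
    rss = np.sum(residuals**2, axis=-1)
    return np.sqrt(rss / dof)


def corrected_tsnr_map(
    data: np.ndarray,
    residuals: np.ndarray,
    dof: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """tSNR after cleanup: raw temporal mean over DOF-corrected residual std."""
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=-1)
    tstd = dof_corrected_tstd(residuals, dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tstd > 0, mean / tstd, np.nan)
    if mask is not None:
        out = np.where(np.asarray(mask).astype(bool), out, np.nan)
    return out


def cv_map(data: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Temporal coefficient of variation in percent: 100·std/mean.

    Identity: cv = 100 / tsnr wherever both are defined.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise DimensionError("data must be 4D (x, y, z, t)")
    if data.shape[-1] < 3:
        raise DimensionError("CV requires at least 3 time points")
    mean = data.mean(axis=-1)
    std = data.std(axis=-1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean != 0, 100.0 * std / mean, np.nan)


def tsnr_ratio_map(
    corrected: np.ndarray,
    raw: np.ndarray,
    threshold: float | None = None,
) -> np.ndarray:
    """Voxelwise corrected/raw tSNR ratio, optionally thresholded.

    With ``threshold`` (conventionally 1.1, i.e. >10% improvement) voxels
    below it are set NaN. The ratio is defined only where raw tSNR > 0.
    """
    corrected = np.asarray(corrected, dtype=float)
    raw = np.asarray(raw, dtype=float)
    if corrected.shape != raw.shape:
        raise DimensionError("corrected and raw maps must share a shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(raw > 0, corrected / raw, np.nan)
    if threshold is not None:
        ratio = np.where(ratio >= threshold, ratio, np.nan)
    return ratio


def mask_summary(map3d: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Mean of a map over the defined, in-mask voxels; returns (mean, count)."""
    map3d = np.asarray(map3d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if map3d.shape != mask.shape:
        raise DimensionError("map and mask shapes differ")
    if not mask.any():
        raise SummaryError("mask is empty")
    values = map3d[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise SummaryError("all in-mask voxels are undefined")
    return float(values.mean()), int(values.size)
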