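"""statsmodels-style front end: PhysioNoiseModel / PhysioNoiseResults.

Typical use::

    model = PhysioNoiseModel(data, recording, timing)   # default 34-reg spec
    res = model.fit()
    print(res.summary())
    res.save("cleaned/")                                # NIfTI maps + JSON

``PhysioNoiseModel`` holds the data and the noise-model configuration;
``fit()`` runs peak detection → phase/rate assignment → slice-wise design →
voxelwise OLS and returns a results object carrying coefficients, residuals,
DOF-corrected tSNR metrics and comparison utilities (nested F-test, BIC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import glm, metrics
from .design import DesignMatrix, NoiseModelSpec, build_design
from .errors import DimensionError
from .io import PeakTrain, PhysioRecording, SliceTiming, detect_cardiac_peaks, read_physio_log
from .phase import PhaseSeries, RateSeries, compute_phase_series, compute_rate_series


class PhysioNoiseModel:
    """Slice-wise physiological noise model for a multi-slice fMRI run.

    Parameters
    ----------
    data : ndarray or nibabel image
        4D time series (x, y, z, t); the z axis must be the slice axis the
        timing refers to.
    recording : PhysioRecording
        Cardiac/respiratory traces and volume triggers on one clock.
    timing : SliceTiming
        Acquisition time of every (volume, slice) pair. No slice-timing
        correction should be applied to the data: the model evaluates phases
        at each slice's true acquisition time instead.
    spec : NoiseModelSpec, optional
        Regressor configuration; defaults to the 34-regressor set.
    mask : ndarray, optional
        3D inclusion mask.
    """

    def __init__(
        self,
        data,
        recording: PhysioRecording,
        timing: SliceTiming,
        spec: NoiseModelSpec | None = None,
        mask: np.ndarray | None = None,
    ) -> None:
        self._affine = np.eye(4)
        if isinstance(data, (nib.Nifti1Image, nib.Nifti2Image)):
            self._affine = data.affine
            data = np.asarray(data.get_fdata())
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionError("data must be 4D (x, y, z, t)")
        if self.data.shape[2] != timing.n_slices:
            raise DimensionError(
                f"data has {self.data.shape[2]} slices, timing declares {timing.n_slices}"
            )
        if self.data.shape[3] != timing.n_volumes:
            raise DimensionError(
                f"data has {self.data.shape[3]} volumes, timing declares {timing.n_volumes}"
            )
        self.recording = recording
        self.timing = timing
        self.spec = spec if spec is not None else NoiseModelSpec.default()
        self.mask = None if mask is None else np.asarray(mask).astype(bool)

    @classmethod
    def from_files(
        cls,
        fmri_path: str | Path,
        physio_path: str | Path,
        tr: float,
        n_slices: int | None = None,
        slice_order: str = "ascending",
        sampling_rate: float = 50.0,
        spec: NoiseModelSpec | None = None,
        mask_path: str | Path | None = None,
        column_spec=None,
    ) -> "PhysioNoiseModel":
        """Build a model from a NIfTI run and a delimited physio log."""
        from .io import extract_slice_times

        img = nib.load(str(fmri_path))
        recording = read_physio_log(
            physio_path, column_spec=column_spec, sampling_rate=sampling_rate
        )
        if n_slices is None:
            n_slices = img.shape[2]
        timing = extract_slice_times(
            recording.triggers, tr=tr, n_slices=n_slices, order=slice_order
        )
        mask = None
        if mask_path is not None:
            mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
        return cls(img, recording, timing, spec=spec, mask=mask)

    def fit(
        self,
        peaks: PeakTrain | None = None,
        min_peak_interval: float = 0.4,
        n_phase_bins: int = 100,
        hr_window: float = 6.0,
    ) -> "PhysioNoiseResults":
        """Detect peaks, build the slice-wise design and fit the GLM."""
        if peaks is None:
            peaks = detect_cardiac_peaks(self.recording, min_interval=min_peak_interval)
        phases = compute_phase_series(
            self.recording, self.timing, cardiac_peaks=peaks, n_bins=n_phase_bins
        )
        needs_rates = self.spec.include_hr or self.spec.include_rvt
        rates = (
            compute_rate_series(
                self.recording, self.timing, cardiac_peaks=peaks, hr_window=hr_window
            )
            if needs_rates
            else None
        )
        design = build_design(self.spec, phases, rates)
        result = glm.fit_nuisance_glm(self.data, design, mask=self.mask)
        return PhysioNoiseResults(
            model=self,
            glm_result=result,
            phases=phases,
            rates=rates,
            design=design,
            peaks=peaks,
        )


@dataclass
class PhysioNoiseResults:
    """Fit outcome: coefficients, residuals, DOF and tSNR accounting."""

    model: PhysioNoiseModel
    glm_result: glm.GLMResult
    phases: PhaseSeries
    rates: RateSeries | None
    design: DesignMatrix
    peaks: PeakTrain

    # ---- basic accessors -------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Per-voxel coefficients, (x, y, z, n_reg); column 0 is the dummy."""
        return self.glm_result.coefficients

    @property
    def resid(self) -> np.ndarray:
        return self.glm_result.residuals

    @property
    def rss(self) -> np.ndarray:
        return self.glm_result.rss

    @property
    def dof(self) -> int:
        """Effective temporal DOF, N − 1 − N_reg."""
        return self.glm_result.dof

    @property
    def n_reg(self) -> int:
        return self.glm_result.n_reg

    @property
    def labels(self) -> list[str]:
        return self.glm_result.labels

    # ---- noise metrics ---------------------------------------------------
    @property
    def tsnr_raw(self) -> np.ndarray:
        return metrics.tsnr_map(self.model.data, mask=self.model.mask)

    @property
    def tstd_corrected(self) -> np.ndarray:
        return metrics.dof_corrected_tstd(self.resid, self.dof)

    @property
    def tsnr_corrected(self) -> np.ndarray:
        return metrics.corrected_tsnr_map(
            self.model.data, self.resid, self.dof, mask=self.model.mask
        )

    def tsnr_ratio(self, threshold: float | None = None) -> np.ndarray:
        """Corrected/raw tSNR map, optionally thresholded (e.g. at 1.1)."""
        return metrics.tsnr_ratio_map(self.tsnr_corrected, self.tsnr_raw, threshold)

    def amplitude(self, prefix: str, order: int = 1) -> np.ndarray:
        """Fitted amplitude sqrt(βsin² + βcos²) of a Fourier pair per voxel."""
        try:
            i = self.labels.index(f"{prefix}_sin_{order}")
            j = self.labels.index(f"{prefix}_cos_{order}")
        except ValueError:
            raise KeyError(f"no {prefix} order-{order} Fourier pair in the design")
        return np.sqrt(self.params[..., i] ** 2 + self.params[..., j] ** 2)

    # ---- model comparison ------------------------------------------------
    def compare_f(self, reduced: "PhysioNoiseResults") -> glm.ModelComparison:
        """Nested F-test of this (full) fit against a reduced fit."""
        return glm.nested_f_test(
            reduced.rss, self.rss, reduced.n_reg, self.n_reg, self.glm_result.n
        )

    def bic_map(self) -> np.ndarray:
        return glm.bic(self.rss, self.n_reg, self.glm_result.n)

    def compare_bic(self, other: "PhysioNoiseResults") -> np.ndarray:
        """Voxelwise preference (1 = this fit, 2 = other) by the BIC rule."""
        return glm.bic_compare(
            self.rss, self.n_reg, other.rss, other.n_reg, self.glm_result.n
        )

    # ---- reporting -------------------------------------------------------
    def mask_mean(self, map3d: np.ndarray, mask: np.ndarray | None = None):
        m = mask if mask is not None else self.model.mask
        if m is None:
            m = np.ones(map3d.shape, dtype=bool)
        return metrics.mask_summary(map3d, m)

    def summary(self) -> str:
        """Plain-text fit summary (shape, DOF accounting, tSNR change)."""
        raw_mean, n_vox = self.mask_mean(self.tsnr_raw)
        corr_mean, _ = self.mask_mean(self.tsnr_corrected)
        ratio = self.tsnr_ratio()
        ratio_med = float(np.nanmedian(ratio))
        spec = self.design.spec
        lines = [
            "Physiological Noise Model Results",
            "=" * 48,
            f"{'Data shape':28s} {self.model.data.shape}",
            f"{'Time points (N)':28s} {self.glm_result.n}",
            f"{'Nuisance regressors':28s} {self.design.n_regressors}",
            f"{'N_reg (incl. dummy)':28s} {self.n_reg}",
            f"{'Effective DOF (N-1-N_reg)':28s} {self.dof}",
            f"{'Basis':28s} {spec.basis}",
            f"{'Cardiac / resp order':28s} {spec.cardiac_order} / {spec.respiratory_order}",
            f"{'Interaction orders':28s} "
            f"{spec.interaction_cardiac_order}x{spec.interaction_respiratory_order}",
            f"{'HR / RVT':28s} {spec.include_hr} / {spec.include_rvt}",
            "-" * 48,
            f"{'Voxels summarized':28s} {n_vox}",
            f"{'Mean raw tSNR':28s} {raw_mean:.2f}",
            f"{'Mean corrected tSNR':28s} {corr_mean:.2f}",
            f"{'Median tSNR ratio':28s} {ratio_med:.3f}",
            "=" * 48,
        ]
        if self.design.degenerate_columns:
            lines.append(
                "Degenerate (all-zero) columns: "
                + ", ".join(self.design.degenerate_columns)
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        """Write residual 4D, tSNR maps and a JSON fit summary; return manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = self.model._affine
        manifest = {}

        def _write(name: str, arr: np.ndarray) -> None:
            p = outdir / name
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), p)
            manifest[name] = str(p)

        _write("residuals.nii.gz", self.resid)
        _write("tsnr_raw.nii.gz", self.tsnr_raw)
        _write("tsnr_corrected.nii.gz", self.tsnr_corrected)
        _write("tsnr_ratio.nii.gz", self.tsnr_ratio())
        _write("tstd_corrected.nii.gz", self.tstd_corrected)
        raw_mean, n_vox = self.mask_mean(self.tsnr_raw)
        corr_mean, _ = self.mask_mean(self.tsnr_corrected)
        summary = {
            "n": self.glm_result.n,
            "n_reg": self.n_reg,
            "dof": self.dof,
            "n_nuisance": self.design.n_regressors,
            "voxels": n_vox,
            "mean_tsnr_raw": raw_mean,
            "mean_tsnr_corrected": corr_mean,
        }
        p = outdir / "fit_summary.json"
        p.write_text(json.dumps(summary, indent=2))
        manifest["fit_summary.json"] = str(p)
        return manifest

    def plot_ratio_histogram(self, ax=None, threshold: float = 1.1):
        """Histogram of the corrected/raw tSNR ratio across defined voxels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.tsnr_ratio()
        vals = vals[np.isfinite(vals)]
        ax.hist(vals, bins=50, color="steelblue")
        ax.axvline(threshold, color="firebrick", linestyle="--",
                   label=f"threshold {threshold}")
        ax.set_xlabel("corrected / raw tSNR")
        ax.set_ylabel("voxels")
        ax.legend()
        return ax
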