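"""Slice-wise nuisance design matrices from phase and rate series.

The default model is the 34-regressor set: 4th-order cardiac and 4th-order
respiratory Fourier expansions (8 + 8 columns), 2×2 multiplicative
interaction orders with sine/cosine of both the sum and difference phase
combinations (16 columns), plus one heart-rate and one RVT column. Columns
are mean-centered but never mutually orthogonalized, so a downstream GLM
apportions shared variance conservatively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError
from .phase import PhaseSeries, RateSeries


@dataclass(frozen=True)
class NoiseModelSpec:
    """Configuration of the physiological noise model.

    Attributes
    ----------
    cardiac_order, respiratory_order : int
        Fourier expansion orders Mc, Mr (2 columns each per order).
    interaction_cardiac_order, interaction_respiratory_order : int
        Interaction orders mc, mr; each (a, b) pair contributes 4 columns
        (sin/cos of a·φc + b·φr and of a·φc − b·φr).
    include_hr, include_rvt : bool
        Add the heart-rate / RVT confound column.
    basis : {"fourier", "fir"}
        Fourier phase expansion (default) or finite-impulse-response phase
        bins, one indicator set per process.
    fir_bins : int
        Bins per cycle when ``basis == "fir"``.
    """

    cardiac_order: int = 4
    respiratory_order: int = 4
    interaction_cardiac_order: int = 2
    interaction_respiratory_order: int = 2
    include_hr: bool = True
    include_rvt: bool = True
    basis: str = "fourier"
    fir_bins: int = 10

    def __post_init__(self) -> None:
        for name in ("cardiac_order", "respiratory_order",
                     "interaction_cardiac_order", "interaction_respiratory_order"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.basis not in ("fourier", "fir"):
            raise ValueError("basis must be 'fourier' or 'fir'")
        if self.basis == "fir" and self.fir_bins < 2:
            raise ValueError("fir_bins must be >= 2")

    @classmethod
    def default(cls) -> "NoiseModelSpec":
        """The 34-regressor demonstration model (4C 4R 2×2X + HR + RVT)."""
        return cls()

    @classmethod
    def harvey(cls) -> "NoiseModelSpec":
        """The 3C4R1X brainstem model: 3 cardiac + 4 respiratory orders and a
        single set of interaction terms, no HR/RVT (18 columns)."""
        return cls(
            cardiac_order=3,
            respiratory_order=4,
            interaction_cardiac_order=1,
            interaction_respiratory_order=1,
            include_hr=False,
            include_rvt=False,
        )

    @property
    def n_regressors(self) -> int:
        return count_regressors(self)

    def to_dict(self) -> dict:
        return {
            "cardiac_order": self.cardiac_order,
            "respiratory_order": self.respiratory_order,
            "interaction_cardiac_order": self.interaction_cardiac_order,
            "interaction_respiratory_order": self.interaction_respiratory_order,
            "include_hr": self.include_hr,
            "include_rvt": self.include_rvt,
            "basis": self.basis,
            "fir_bins": self.fir_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModelSpec":
        return cls(**d)


def count_regressors(spec: NoiseModelSpec) -> int:
    """Number of nuisance columns the design builder will emit.

    Fourier basis: 2·Mc + 2·Mr + 4·mc·mr + [HR] + [RVT]. The default spec
    gives 8 + 8 + 16 + 1 + 1 = 34. FIR basis: one indicator set per process
    with the last bin dropped (it is redundant next to an intercept), i.e.
    2·(fir_bins − 1) + [HR] + [RVT].
    """
    extra = int(spec.include_hr) + int(spec.include_rvt)
    if spec.basis == "fir":
        return 2 * (spec.fir_bins - 1) + extra
    return (
        2 * spec.cardiac_order
        + 2 * spec.respiratory_order
        + 4 * spec.interaction_cardiac_order * spec.interaction_respiratory_order
        + extra
    )


def fourier_regressors(phases: np.ndarray, order: int) -> np.ndarray:
    """Columns sin(mφ), cos(mφ) for m = 1..order; shape (n, 2·order)."""
    if order < 0:
        raise ValueError("order must be >= 0")
    phi = np.asarray(phases, dtype=float).ravel()
    cols = []
    for m in range(1, order + 1):
        cols.append(np.sin(m * phi))
        cols.append(np.cos(m * phi))
    if not cols:
        return np.empty((phi.size, 0))
    return np.column_stack(cols)


def fourier_labels(prefix: str, order: int) -> list[str]:
    out = []
    for m in range(1, order + 1):
        out += [f"{prefix}_sin_{m}", f"{prefix}_cos_{m}"]
    return out


def interaction_regressors(
    cardiac_phase: np.ndarray,
    respiratory_phase: np.ndarray,
    mc: int,
    mr: int,
) -> np.ndarray:
    """Cardio-respiratory interaction columns, 4 per order pair.

    For each (a, b) with a ≤ mc, b ≤ mr the columns are sin/cos of
    a·φc + b·φr and of a·φc − b·φr; these are the sum/difference sidebands
    of the coupled processes.
    """
    phic = np.asarray(cardiac_phase, dtype=float).ravel()
    phir = np.asarray(respiratory_phase, dtype=float).ravel()
    if phic.shape != phir.shape:
        raise DimensionError("cardiac and respiratory phase lengths differ")
    cols = []
    for a in range(1, mc + 1):
        for b in range(1, mr + 1):
            s = a * phic + b * phir
            d = a * phic - b * phir
            cols += [np.sin(s), np.cos(s), np.sin(d), np.cos(d)]
    if not cols:
        return np.empty((phic.size, 0))
    return np.column_stack(cols)


def interaction_labels(mc: int, mr: int) -> list[str]:
    out = []
    for a in range(1, mc + 1):
        for b in range(1, mr + 1):
            out += [
                f"interaction_sin_sum_{a}_{b}",
                f"interaction_cos_sum_{a}_{b}",
                f"interaction_sin_diff_{a}_{b}",
                f"interaction_cos_diff_{a}_{b}",
            ]
    return out


def fir_bin_regressors(phases: np.ndarray, n_bins: int) -> np.ndarray:
    """Indicator columns assigning each sample to a fraction of the cycle.

    Phases are shifted to [0, 2π); bin b spans
    [b·2π/n_bins, (b+1)·2π/n_bins). Each row contains exactly one 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    phi = np.mod(np.asarray(phases, dtype=float).ravel(), 2 * np.pi)
    idx = np.clip((phi / (2 * np.pi / n_bins)).astype(int), 0, n_bins - 1)
    out = np.zeros((phi.size, n_bins))
    out[np.arange(phi.size), idx] = 1.0
    return out


@dataclass
class DesignMatrix:
    """Per-slice nuisance design with shared column labels.

    ``matrices[s]`` is the (n_volumes × n_regressors) design of slice ``s``;
    the column layout is identical across slices. Columns are mean-centered.
    """

    matrices: list[np.ndarray]
    labels: list[str]
    spec: NoiseModelSpec
    degenerate_columns: list[str] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.matrices)

    @property
    def n_regressors(self) -> int:
        return len(self.labels)

    def write(self, outdir: str | Path) -> list[Path]:
        """One whitespace-delimited text file per slice plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for s, mat in enumerate(self.matrices):
            p = outdir / f"design_slice{s:03d}.txt"
            header = "\t".join(self.labels)
            np.savetxt(p, mat, header=header, comments="", delimiter="\t")
            paths.append(p)
        sidecar = outdir / "noise_model.json"
        sidecar.write_text(json.dumps(self.spec.to_dict(), indent=2))
        paths.append(sidecar)
        return paths

    @classmethod
    def read(cls, indir: str | Path) -> "DesignMatrix":
        indir = Path(indir)
        spec = NoiseModelSpec.from_dict(
            json.loads((indir / "noise_model.json").read_text())
        )
        matrices, labels = [], None
        for p in sorted(indir.glob("design_slice*.txt")):
            with open(p) as fh:
                labels = fh.readline().strip().split("\t")
            mat = np.loadtxt(p, skiprows=1, ndmin=2)
            matrices.append(mat)
        if labels is None:
            raise DimensionError(f"no design_slice*.txt files in {indir}")
        return cls(matrices=matrices, labels=labels, spec=spec)


def _slice_columns(
    spec: NoiseModelSpec,
    phic: np.ndarray,
    phir: np.ndarray,
    hr: np.ndarray | None,
    rvt: np.ndarray | None,
) -> tuple[np.ndarray, list[str]]:
    blocks, labels = [], []
    if spec.basis == "fourier":
        blocks.append(fourier_regressors(phic, spec.cardiac_order))
        labels += fourier_labels("cardiac", spec.cardiac_order)
        blocks.append(fourier_regressors(phir, spec.respiratory_order))
        labels += fourier_labels("respiratory", spec.respiratory_order)
        mc, mr = spec.interaction_cardiac_order, spec.interaction_respiratory_order
        blocks.append(interaction_regressors(phic, phir, mc, mr))
        labels += interaction_labels(mc, mr)
    else:
        # drop the last bin of each set: with all bins each set sums to the
        # intercept, which would make the GLM design rank deficient
        cb = fir_bin_regressors(phic, spec.fir_bins)[:, :-1]
        rb = fir_bin_regressors(phir, spec.fir_bins)[:, :-1]
        blocks += [cb, rb]
        labels += [f"cardiac_bin_{b}" for b in range(spec.fir_bins - 1)]
        labels += [f"respiratory_bin_{b}" for b in range(spec.fir_bins - 1)]
    if spec.include_hr:
        if hr is None:
            raise DimensionError("spec includes HR but no HR series given")
        blocks.append(hr[:, None])
        labels.append("hr")
    if spec.include_rvt:
        if rvt is None:
            raise DimensionError("spec includes RVT but no RVT series given")
        blocks.append(rvt[:, None])
        labels.append("rvt")
    mat = np.hstack([b for b in blocks]) if blocks else np.empty((phic.size, 0))
    return mat, labels


def build_design(
    spec: NoiseModelSpec,
    phases: PhaseSeries,
    rates: RateSeries | None = None,
) -> DesignMatrix:
    """Per-slice nuisance design matrices, mean-centered, labels attached.

    Column order: cardiac Fourier | respiratory Fourier | interactions |
    HR | RVT. Column count equals :func:`count_regressors`. Columns that are
    identically zero before centering (e.g. from degenerate phases) are kept
    but reported in ``degenerate_columns``.
    """
    phic_all, phir_all = phases.cardiac, phases.respiratory
    if phic_all.shape != phir_all.shape:
        raise DimensionError("phase series shapes differ")
    n_volumes, n_slices = phic_all.shape
    if rates is not None and rates.hr.shape != phic_all.shape:
        raise DimensionError("rate series shape does not match phase series")
    matrices, labels = [], None
    degenerate: set[str] = set()
    for s in range(n_slices):
        hr = rates.hr[:, s] if rates is not None else None
        rvt = rates.rvt[:, s] if rates is not None else None
        mat, labels = _slice_columns(spec, phic_all[:, s], phir_all[:, s], hr, rvt)
        if mat.shape[1] != count_regressors(spec):
            raise DimensionError(
                f"built {mat.shape[1]} columns, expected {count_regressors(spec)}"
            )
        zero = np.all(np.abs(mat) < 1e-12, axis=0)
        for j in np.where(zero)[0]:
            degenerate.add(labels[j])
        mat = mat - mat.mean(axis=0, keepdims=True)
        matrices.append(mat)
    return DesignMatrix(
        matrices=matrices,
        labels=labels if labels is not None else [],
        spec=spec,
        degenerate_columns=sorted(degenerate),
    )
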