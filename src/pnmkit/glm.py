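"""Voxelwise nuisance regression, DOF accounting and model comparison.

The nuisance GLM is ordinary least squares per voxel against an intercept
("dummy") column plus the slice's nuisance columns. Regressors are not
orthogonalized, so shared variance is apportioned by the solver itself and
the cleanup is conservative. The effective degrees of freedom follow the
N − 1 − N_reg accounting, where N_reg counts the dummy regressor.

Model comparison offers a nested F-test over extra regressors and the
Bayesian Information Criterion BIC(k, N) = N·log(RSS/N) + k·log(N) (natural
log) for non-nested alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignMatrix
from .errors import DimensionError, DOFError, NestingError, RankError


def effective_dof(n: int, n_reg: int) -> int:
    """Effective temporal degrees of freedom: N − 1 − N_reg.

    ``n_reg`` includes the dummy/intercept regressor. Requires
    ``n_reg <= n − 2`` so at least one degree of freedom remains.
    """
    if n_reg > n - 2:
        raise DOFError(
            f"{n_reg} regressors leave no degrees of freedom for {n} time points"
        )
    return n - 1 - n_reg


@dataclass
class GLMResult:
    """Per-voxel outcome of the nuisance regression.

    Attributes
    ----------
    coefficients : ndarray, shape (nx, ny, nz, n_reg)
        OLS coefficients; column 0 is the intercept.
    residuals : ndarray, shape (nx, ny, nz, n)
        Residual time series (NaN outside the mask).
    rss : ndarray, shape (nx, ny, nz)
        Residual sum of squares.
    n, n_reg, dof : int
        Time points, regressor count (incl. intercept), N − 1 − N_reg.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    rss: np.ndarray
    n: int
    n_reg: int
    dof: int
    labels: list[str]


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns implicated via the smallest right-singular vector
        _, _, vt = np.linalg.svd(X)
        weights = np.abs(vt[-1])
        guilty = [labels[j] for j in np.argsort(weights)[::-1][:4] if weights[j] > 1e-3]
        raise RankError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns likely include: {', '.join(guilty)}"
        )


def fit_nuisance_glm(
    data: np.ndarray,
    designs: DesignMatrix,
    mask: np.ndarray | None = None,
    add_intercept: bool = True,
) -> GLMResult:
    """OLS-fit the slice-wise nuisance model to a 4D series.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n)
        Voxel time series; slice index is the 3rd axis and selects the
        per-slice design.
    designs : DesignMatrix
        One nuisance matrix per slice (see :func:`pnmkit.design.build_design`).
    mask : ndarray, optional
        Boolean/0-1 3D array; voxels outside are skipped and reported NaN.
    add_intercept : bool
        Prepend the dummy/intercept column (the N − 1 − N_reg accounting
        counts it; disable only for pre-demeaned data).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise DimensionError("data must be 4D (x, y, z, t)")
    nx, ny, nz, n = data.shape
    if designs.n_slices != nz:
        raise DimensionError(
            f"{designs.n_slices} slice designs for {nz} data slices"
        )
    if designs.matrices and designs.matrices[0].shape[0] != n:
        raise DimensionError(
            f"design has {designs.matrices[0].shape[0]} rows for {n} volumes"
        )
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (nx, ny, nz):
            raise DimensionError("mask shape does not match data")
    k_nuis = designs.n_regressors
    n_reg = k_nuis + (1 if add_intercept else 0)
    dof = effective_dof(n, n_reg)
    labels = (["intercept"] if add_intercept else []) + list(designs.labels)

    coefficients = np.full((nx, ny, nz, n_reg), np.nan)
    residuals = np.full((nx, ny, nz, n), np.nan)
    rss = np.full((nx, ny, nz), np.nan)

    for s in range(nz):
        X = designs.matrices[s]
        if add_intercept:
            X = np.column_stack([np.ones(n), X])
        _check_rank(X, labels)
        sl = data[:, :, s, :]
        if mask is not None:
            vox = np.where(mask[:, :, s])
            if vox[0].size == 0:
                continue
            Y = sl[vox[0], vox[1], :].T  # (n, nvox)
        else:
            Y = sl.reshape(-1, n).T
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        res = Y - X @ beta
        r = np.sum(res**2, axis=0)
        if mask is not None:
            coefficients[vox[0], vox[1], s, :] = beta.T
            residuals[vox[0], vox[1], s, :] = res.T
            rss[vox[0], vox[1], s] = r
        else:
            coefficients[:, :, s, :] = beta.T.reshape(nx, ny, n_reg)
            residuals[:, :, s, :] = res.T.reshape(nx, ny, n)
            rss[:, :, s] = r.reshape(nx, ny)

    return GLMResult(
        coefficients=coefficients,
        residuals=residuals,
        rss=rss,
        n=n,
        n_reg=n_reg,
        dof=dof,
        labels=labels,
    )


@dataclass
class ModelComparison:
    """Voxelwise nested-model comparison."""

    f_stat: np.ndarray
    p_value: np.ndarray
    f_dof_num: int
    f_dof_den: int


def nested_f_test(
    rss0: np.ndarray,
    rss1: np.ndarray,
    k0: int,
    k1: int,
    n: int,
    tol: float = 1e-8,
) -> ModelComparison:
    """F-test of whether the k1 − k0 extra regressors are beneficial.

    F = ((RSS0 − RSS1)/(k1 − k0)) / (RSS1/(N − 1 − k1)), referred to the F
    distribution with (k1 − k0, N − 1 − k1) degrees of freedom. Regressor
    counts follow the same convention as :func:`effective_dof` (the dummy
    regressor is counted).
    """
    if k1 <= k0:
        raise NestingError(f"k1 ({k1}) must exceed k0 ({k0})")
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.asarray(rss1, dtype=float)
    if rss0.shape != rss1.shape:
        raise DimensionError("rss0 and rss1 shapes differ")
    scale = np.nanmax(np.abs(rss0)) if rss0.size else 1.0
    if np.any(rss1 > rss0 + tol * max(scale, 1.0)):
        raise NestingError("rss1 exceeds rss0: models are not nested")
    dof_den = effective_dof(n, k1)
    dof_num = k1 - k0
    diff = np.clip(rss0 - rss1, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (diff / dof_num) / (rss1 / dof_den)
    p = stats.f.sf(f, dof_num, dof_den)
    return ModelComparison(f_stat=f, p_value=p, f_dof_num=dof_num, f_dof_den=dof_den)


def fdr_threshold(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg rejection mask over defined voxelwise p-values.

    Optional multiplicity control for F-maps; by default maps are reported
    uncorrected and judged by the spatial pattern of benefit. NaN entries
    (masked voxels) are ignored and returned False.
    """
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    reject = np.zeros(flat.size, dtype=bool)
    if ok.any():
        pv = flat[ok]
        order = np.argsort(pv)
        m = pv.size
        below = pv[order] <= alpha * (np.arange(1, m + 1) / m)
        k_max = np.nonzero(below)[0].max() + 1 if below.any() else 0
        rej = np.zeros(m, dtype=bool)
        rej[order[:k_max]] = True
        reject[ok] = rej
    return reject.reshape(p.shape)


def bic(rss: np.ndarray, k: int, n: int) -> np.ndarray:
    """BIC(k, N) = N·log(RSS/N) + k·log(N), natural logarithm.

    A voxel with RSS = 0 is a degenerate (interpolating) fit; it is returned
    as −inf so it is excluded from meaningful comparisons.
    """
    if n <= 1:
        raise DOFError("BIC requires n > 1")
    rss = np.asarray(rss, dtype=float)
    out = np.full(rss.shape, -np.inf)
    ok = rss > 0
    with np.errstate(divide="ignore"):
        out[ok] = n * np.log(rss[ok] / n) + k * np.log(n)
    if rss.ndim == 0:
        return float(out)
    return out


def bic_compare(
    rss1: np.ndarray,
    k1: int,
    rss2: np.ndarray,
    k2: int,
    n: int,
) -> np.ndarray:
    """Voxelwise model preference (1 or 2) by the BIC inequality.

    Model 1 is superior when log(RSS1/RSS2) < (k2 − k1)·log(N)/N. Equality is
    resolved by parsimony: the larger model is never preferred on a tie.
    """
    scalar = np.ndim(rss1) == 0 and np.ndim(rss2) == 0
    rss1 = np.atleast_1d(np.asarray(rss1, dtype=float))
    rss2 = np.atleast_1d(np.asarray(rss2, dtype=float))
    if rss1.shape != rss2.shape:
        raise DimensionError("rss arrays must share a shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        lhs = np.log(rss1 / rss2)
    rhs = (k2 - k1) * np.log(n) / n
    pref = np.where(lhs < rhs, 1, 2)
    pref[lhs == rhs] = 1 if k1 <= k2 else 2
    return int(pref[0]) if scalar else pref
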