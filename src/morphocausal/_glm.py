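"""Vectorized mass-univariate ordinary-least-squares machinery.

All voxelwise statistics in the package reduce to the t statistic of one
coefficient in ``Y = X b + e`` fitted independently per voxel column of Y.
"""

from __future__ import annotations

import numpy as np


def check_full_rank(X: np.ndarray, column_names: list[str] | None = None) -> None:
    """Raise ``ValueError`` naming (nearly) collinear columns if X is rank
    deficient."""
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if column_names is None:
            column_names = [f"col{i}" for i in range(X.shape[1])]
        # identify columns whose removal restores full relative rank
        suspects = []
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                suspects.append(column_names[j])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns); collinear columns involve: {', '.join(suspects)}"
        )


def glm_contrast_t(
    Y: np.ndarray, X: np.ndarray, contrast: np.ndarray | int
) -> tuple[np.ndarray, int, np.ndarray]:
    """t statistic of a contrast of coefficients, per column of Y.

    Parameters
    ----------
    Y : (n, v) response matrix (one column per voxel).
    X : (n, p) full-rank design matrix.
    contrast : length-p vector c, or an integer column index (elementary
        contrast).

    Returns
    -------
    t : (v,) t values (NaN at degenerate columns).
    df : residual degrees of freedom ``n - p``.
    degenerate : (v,) boolean, True where the residual variance is zero so
        the t statistic is undefined.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y rows must match design rows")
    if isinstance(contrast, (int, np.integer)):
        c = np.zeros(p)
        c[int(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=float)
    check_full_rank(X)
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    P = XtX_inv @ X.T  # (p, n)
    beta = P @ Y  # (p, v)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c_var = float(c @ XtX_inv @ c)
    # zero residual variance up to round-off relative to the response scale
    scale = np.abs(Y).max(axis=0) + 1.0
    degenerate = sigma2 <= (1e-10 * scale) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * c_var)
        t = (c @ beta) / se
    t[degenerate] = np.nan
    return t, df, degenerate


def residualize(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y after OLS on Z (Z should include an
    intercept column if one is wanted)."""
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    return Y - Z @ beta
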