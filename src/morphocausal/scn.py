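"""Seed-based structural covariance network (SCN) mapping.

Structural covariance asks which voxels' GMV co-varies, across subjects,
with the mean GMV of a seed region.  Two models are provided because the
group question can be posed two ways: a within-group covariance map
(t of the seed regressor among patients only) and a seed-by-group
interaction map (does the seed-voxel slope differ between patients and
controls).  Voxelwise p values are corrected with Benjamini-Hochberg FDR
over in-mask voxels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from ._glm import glm_contrast_t
from .datasets import GMVDataset
from .vbm import StatMap


def _covariate_block(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return covariates


def seed_covariance_map(
    dataset: GMVDataset,
    seed_values: np.ndarray,
    covariates: np.ndarray | None = None,
) -> StatMap:
    """Within-group covariance map: per voxel, the t of the seed regressor
    in OLS of voxel GMV on ``[intercept, seed, covariates...]``."""
    seed_values = np.asarray(seed_values, dtype=float)
    if len(seed_values) != dataset.n_subjects:
        raise ValueError("seed_values must align with dataset rows")
    if seed_values.std() == 0:
        raise ValueError("seed regressor is constant")
    n = dataset.n_subjects
    X = np.column_stack([np.ones(n), seed_values, _covariate_block(covariates, n)])
    t, df, degenerate = glm_contrast_t(dataset.data, X, 1)
    return StatMap(values=t, df=df, stat_kind="t", mask=dataset.mask,
                   affine=dataset.affine, degenerate=degenerate)


def scn_group_interaction(
    dataset: GMVDataset,
    seed_values: np.ndarray,
    group_labels: Sequence[str] | np.ndarray,
    covariates: np.ndarray | None = None,
) -> StatMap:
    """Seed-by-group interaction map.

    Per voxel, the t of the ``seed x group`` term in OLS on
    ``[intercept, group, seed, seed x group, covariates...]`` — positive t
    means a steeper seed-voxel slope in the group coded 1.
    """
    seed_values = np.asarray(seed_values, dtype=float)
    group = np.asarray(group_labels)
    if len(seed_values) != dataset.n_subjects or len(group) != dataset.n_subjects:
        raise ValueError("seed_values and group_labels must align with dataset rows")
    uniq = np.unique(group)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    g = (group == uniq[-1]).astype(float)
    for val in (0.0, 1.0):
        if (g == val).sum() < 3:
            raise ValueError("each group needs at least 3 subjects")
    n = dataset.n_subjects
    X = np.column_stack([
        np.ones(n), g, seed_values, seed_values * g, _covariate_block(covariates, n)
    ])
    t, df, degenerate = glm_contrast_t(dataset.data, X, 3)
    return StatMap(values=t, df=df, stat_kind="t", mask=dataset.mask,
                   affine=dataset.affine, degenerate=degenerate)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject the i* smallest p values where
    i* is the largest i with p(i) <= (i/m) q.  Returns a boolean rejection
    array aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) / m) * q
    if not below.any():
        return reject
    k = int(np.max(np.nonzero(below)[0])) + 1
    reject[order[:k]] = True
    return reject


def statmap_fdr(statmap: StatMap, q: float = 0.05) -> np.ndarray:
    """FDR-significant voxels of a t map (two-tailed), over non-degenerate
    in-mask voxels only."""
    ok = ~statmap.degenerate
    p = np.ones_like(statmap.values)
    p[ok] = 2 * stats.t.sf(np.abs(statmap.values[ok]), statmap.df)
    reject = np.zeros_like(ok)
    reject[ok] = fdr_bh(p[ok], q)
    return reject
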