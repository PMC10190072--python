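"""Voxel-based morphometry: covariate-adjusted group comparison of GMV with
permutation cluster-extent correction, duration-stage statistics, and the
demographic summary tests.

The voxelwise model is an ordinary-least-squares fit of each voxel's GMV on
``[intercept, group, age, sex, TIV]``; the reported statistic is the t of
the group coefficient (coded patient = 1, control = 0, so positive t means
patient hypertrophy).  Cluster-level family-wise error is controlled by a
Freedman-Lane permutation of covariate-adjusted residuals: the null
distribution of the maximum suprathreshold cluster size is built by
refitting the model on permuted data, and a cluster is significant when its
exact permutation p-value (1 + #{null >= size}) / (n_perm + 1) is at or
below the family-wise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._glm import check_full_rank, glm_contrast_t, residualize
from .datasets import GMVDataset, SubjectRecord, GROUP_PATIENT, records_to_frame

DEFAULT_COVARIATES = ("age", "sex", "tiv")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Per-subject design with named columns; rows aligned with the
    GMVDataset subject order."""

    matrix: np.ndarray
    columns: list[str]
    contrast_column: str = "group"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names must match matrix width")
        check_full_rank(self.matrix, self.columns)

    @property
    def contrast_index(self) -> int:
        return self.columns.index(self.contrast_column)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame | Sequence[SubjectRecord],
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ) -> "DesignMatrix":
        """Build ``[intercept, group, covariates...]`` from a subject table.

        ``sex`` is encoded male = 1, female = 0; ``group`` patient = 1,
        control = 0.
        """
        frame = table if isinstance(table, pd.DataFrame) else records_to_frame(table)
        cols = [np.ones(len(frame)), (frame["group"] == GROUP_PATIENT).to_numpy(float)]
        names = ["intercept", "group"]
        for cov in covariates:
            if cov == "sex":
                cols.append((frame["sex"] == "male").to_numpy(float))
            else:
                cols.append(frame[cov].to_numpy(float))
            names.append(cov)
        return cls(np.column_stack(cols), names)


# ---------------------------------------------------------------------------
# voxelwise t map
# ---------------------------------------------------------------------------

@dataclass
class StatMap:
    """A voxelwise statistic image over the in-mask voxels."""

    values: np.ndarray
    df: int
    stat_kind: str
    mask: np.ndarray
    affine: np.ndarray
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape, dtype=bool)

    def to_grid(self, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        vals = np.where(self.degenerate, fill, self.values)
        out[self.mask] = np.nan_to_num(vals, nan=fill)
        return out


def two_sample_t_map(dataset: GMVDataset, design: DesignMatrix) -> StatMap:
    """Covariate-adjusted two-sample t map of the group effect.

    Voxels with zero residual variance are flagged degenerate and carry a
    NaN statistic; they are excluded from thresholding downstream.
    """
    group_col = design.matrix[:, design.contrast_index]
    uniq, counts = np.unique(group_col, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, df, degenerate = glm_contrast_t(dataset.data, design.matrix, design.contrast_index)
    return StatMap(values=t, df=df, stat_kind="t", mask=dataset.mask,
                   affine=dataset.affine, degenerate=degenerate)


# ---------------------------------------------------------------------------
# permutation cluster correction
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    voxels: np.ndarray            # (k, 3) grid indices
    size: int
    peak_stat: float
    peak_mm: np.ndarray
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    voxel_p_threshold: float
    cluster_alpha: float
    t_threshold: float
    null_max_sizes: np.ndarray
    method: str = "permutation"

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": i + 1,
                "size_voxels": c.size,
                "peak_stat": c.peak_stat,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "cluster_p": c.p_value,
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster", "size_voxels", "peak_stat", "peak_x_mm",
                     "peak_y_mm", "peak_z_mm", "cluster_p"],
        )

    def cluster_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for c in self.clusters:
            out[tuple(c.voxels.T)] = True
        return out


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def _max_cluster_size(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_correct(
    statmap: StatMap,
    dataset: GMVDataset,
    design: DesignMatrix,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    rng_seed: int = 0,
    connectivity: int = 26,
) -> ClusterResult:
    """Cluster-extent correction of a t map by label permutation.

    The forming threshold is the two-tailed ``voxel_p`` quantile of
    t(df); connected components (26-neighbourhood by default) of
    ``|t| > threshold`` are evaluated against the permutation null of the
    maximum cluster size.  Covariates are held fixed via Freedman-Lane
    residual permutation.  Deterministic under ``rng_seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    structure = _connectivity_structure(connectivity)
    df = statmap.df
    t_thr = float(stats.t.isf(voxel_p / 2.0, df))

    tvals = np.where(statmap.degenerate, 0.0, np.nan_to_num(statmap.values))
    supra = np.zeros(dataset.mask.shape, dtype=bool)
    supra[dataset.mask] = np.abs(tvals) > t_thr
    labels, n_clusters = ndimage.label(supra, structure=structure)

    # Freedman-Lane null: fit the covariate-only model, permute its
    # residuals, and refit the full model.
    rng = np.random.default_rng(rng_seed)
    X = design.matrix
    ci = design.contrast_index
    Z = np.delete(X, ci, axis=1)
    fitted_Z = dataset.data - residualize(dataset.data, Z)
    resid_Z = dataset.data - fitted_Z

    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    P = XtX_inv @ X.T
    c = np.zeros(p)
    c[ci] = 1.0
    c_var = float(c @ XtX_inv @ c)
    cP = c @ P  # (n,)

    null_max = np.empty(n_perm, dtype=int)
    grid = np.zeros(dataset.mask.shape, dtype=bool)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yb = fitted_Z + resid_Z[perm]
        beta = P @ Yb
        resid = Yb - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = (cP @ Yb) / np.sqrt(sigma2 * c_var)
        grid[:] = False
        grid[dataset.mask] = np.abs(np.nan_to_num(tb)) > t_thr
        null_max[b] = _max_cluster_size(grid, structure)

    coords_mm = dataset.voxel_coordinates_mm()
    flat_pos = np.cumsum(dataset.mask.ravel()) - 1
    clusters: list[Cluster] = []
    for lab in range(1, n_clusters + 1):
        vox = np.argwhere(labels == lab)
        size = len(vox)
        p_clu = float((1 + np.sum(null_max >= size)) / (n_perm + 1))
        if p_clu > cluster_alpha:
            continue
        cols = flat_pos[np.ravel_multi_index(tuple(vox.T), dataset.mask.shape)]
        vals = tvals[cols]
        peak_local = int(np.argmax(np.abs(vals)))
        clusters.append(Cluster(
            voxels=vox, size=size,
            peak_stat=float(vals[peak_local]),
            peak_mm=coords_mm[cols[peak_local]],
            p_value=p_clu,
        ))
    clusters.sort(key=lambda cl: -cl.size)
    return ClusterResult(
        clusters=clusters, voxel_p_threshold=voxel_p, cluster_alpha=cluster_alpha,
        t_threshold=t_thr, null_max_sizes=null_max,
    )


# ---------------------------------------------------------------------------
# demographics statistics
# ---------------------------------------------------------------------------

def chisq_from_counts(table: np.ndarray) -> float:
    """Pearson chi-square Σ(O−E)²/E on a 2x2 count table, no continuity
    correction (the convention that reproduces demographic-table values)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ValueError("zero marginal: chi-square undefined")
    expected = row @ col / total
    return float(((obs - expected) ** 2 / expected).sum())


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-variance two-sample t from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("sds must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise ValueError("both SDs zero with equal means: t undefined")
        return float(np.inf) if mean1 > mean2 else float(-np.inf)
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    return float((mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def qc_exclude(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Drop subjects flagged as QC failures (order preserved)."""
    return [r for r in records if not r.qc_excluded]


# ---------------------------------------------------------------------------
# duration stages and ROI statistics
# ---------------------------------------------------------------------------

@dataclass
class StageSplit:
    boundary_months: float
    short_ids: list[str]
    long_ids: list[str]

    @property
    def n_short(self) -> int:
        return len(self.short_ids)

    @property
    def n_long(self) -> int:
        return len(self.long_ids)


def stage_split(
    records: Sequence[SubjectRecord], boundary_months: float = 60.0
) -> StageSplit:
    """Partition patients into short (< boundary) and long (>= boundary)
    illness-duration stages; the boundary itself belongs to the long stage."""
    short_ids, long_ids = [], []
    for r in records:
        if r.group != GROUP_PATIENT:
            continue
        if r.duration_months < 6.0:
            raise ValueError(
                f"{r.subject_id}: duration {r.duration_months} < 6 months "
                "violates the inclusion criterion"
            )
        (long_ids if r.duration_months >= boundary_months else short_ids).append(
            r.subject_id
        )
    return StageSplit(boundary_months=boundary_months,
                      short_ids=short_ids, long_ids=long_ids)


def extract_roi_mean(dataset: GMVDataset, region: np.ndarray) -> np.ndarray:
    """Per-subject mean GMV over a 3-D boolean region ⊆ mask."""
    cols = dataset.region_columns(region)
    if cols.size == 0:
        raise ValueError("region is empty")
    return dataset.data[:, cols].mean(axis=1)


@dataclass
class AncovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_residual: int
    pairwise: pd.DataFrame  # contrast, t, df, p_raw, p_bonferroni


def roi_ancova(
    values: np.ndarray,
    groups: Sequence[str],
    covariates: np.ndarray | None = None,
) -> AncovaResult:
    """ANCOVA of an ROI mean across three (or more) groups with pairwise
    covariate-adjusted post-hoc t tests, Bonferroni corrected.

    F tests the group factor after covariate adjustment (extra sum of
    squares of the group dummies — equivalent to Type III for a single
    factor without interactions).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")
    for lev in levels:
        if int((groups == lev).sum()) < 2:
            raise ValueError(f"group level {lev!r} has fewer than 2 subjects")
    n = len(values)
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    Z = np.column_stack([np.ones(n), covariates])
    check_full_rank(Z)
    dummies = np.column_stack([(groups == lev).astype(float) for lev in levels[1:]])
    X_full = np.column_stack([Z, dummies])
    check_full_rank(X_full)

    def _rss(X):
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        r = values - X @ beta
        return float(r @ r)

    rss_red, rss_full = _rss(Z), _rss(X_full)
    q = dummies.shape[1]
    df_resid = n - X_full.shape[1]
    F = ((rss_red - rss_full) / q) / (rss_full / df_resid)
    p = float(stats.f.sf(F, q, df_resid))

    n_pairs = len(levels) * (len(levels) - 1) // 2
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            sel = (groups == levels[i]) | (groups == levels[j])
            y = values[sel]
            d = (groups[sel] == levels[j]).astype(float)
            Xp = np.column_stack([np.ones(sel.sum()), d, covariates[sel]])
            t, df, _ = glm_contrast_t(y[:, None], Xp, 1)
            t = float(t[0])
            p_raw = float(2 * stats.t.sf(abs(t), df))
            rows.append({
                "contrast": f"{levels[j]} - {levels[i]}",
                "t": t, "df": df, "p_raw": p_raw,
                "p_bonferroni": min(1.0, n_pairs * p_raw),
            })
    return AncovaResult(
        f_statistic=float(F), p_value=p, df_between=q, df_residual=df_resid,
        pairwise=pd.DataFrame(rows),
    )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on ``[1, covariates]`` by OLS; the
    Pearson r of the residuals is returned with its two-tailed p from the
    t transform at ``df = n - k - 2`` (k covariates).  With no covariates
    this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    k = covariates.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    Z = np.column_stack([np.ones(n), covariates])
    rx = residualize(x[:, None], Z)[:, 0]
    ry = residualize(y[:, None], Z)[:, 0]
    if np.allclose(rx, 0) or np.allclose(ry, 0) or rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_ = np.clip(r, -1.0, 1.0)
    if abs(r_) == 1.0:
        return r_, 0.0
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r_, p
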