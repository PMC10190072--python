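"""Causal structural covariance: duration-ordered pseudo-time-series
Granger causality on gray-matter volume.

Cross-sectional GMV maps carry no time axis; ordering patients by ascending
illness duration grants the cohort a pseudo-time axis along which lagged
(Granger-style) regression becomes meaningful.  The causal statistic is the
*signed path coefficient*: with both series standardized, the coefficient
of the lagged seed series in

    y_t = a + sum_k b_k y_{t-k} + sum_k c_k x_{t-k} + e_t

(default autoregressive order 1, so the statistic is c_1).  A positive
value means the target changes in the same direction as the seed did one
step earlier in the duration ordering; a negative value, the opposite
direction.  On standardized series the coefficient is scale-free, which is
what makes a fixed |GC| cut meaningful.

Voxelwise maps are z-scored across in-mask voxels and thresholded
conjunctively: |z| > z_min, |GC| > gc_abs_min, and Benjamini-Hochberg FDR
on the two-tailed normal p of z.  A KPSS level-stationarity screen runs
before the causal fit; by default nonstationary series are flagged and
kept (a trending disease signal is nonstationary by design), with
differencing and detrending available as remedies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from ._glm import residualize
from .datasets import GMVDataset, SubjectRecord, GROUP_PATIENT
from .scn import fdr_bh


@dataclass
class CascnConfig:
    """Tunables of the causal analysis (defaults follow the published
    voxelwise convention: order-1 autoregression, z > 2.3, |GC| > 0.16,
    FDR q = 0.05, stationarity reported but not remedied)."""

    model_order: int = 1
    stationarity_remedy: str = "report_only"  # report_only | difference | detrend
    kpss_alpha: float = 0.05
    z_min: float = 2.3
    gc_abs_min: float = 0.16
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if self.model_order < 1:
            raise ValueError("model_order must be >= 1")
        if self.stationarity_remedy not in ("report_only", "difference", "detrend"):
            raise ValueError(f"unknown stationarity_remedy {self.stationarity_remedy!r}")


@dataclass
class PseudoTimeSeries:
    """Duration-ordered, covariate-residualized, standardized patient GMV.

    ``series`` is voxels x ordered-patients with each voxel's series at
    mean 0 / SD 1 (degenerate zero-variance voxels flagged and zeroed);
    ``resid_series`` is the same matrix before standardization, kept so
    ROI averages can be formed on a common scale and re-standardized.
    """

    order: np.ndarray            # positions into the original patient rows
    subject_ids: list[str]       # in pseudo-time order
    durations: np.ndarray        # months, non-decreasing
    series: np.ndarray           # (n_voxels, T) standardized
    resid_series: np.ndarray     # (n_voxels, T) residualized only
    mask: np.ndarray
    affine: np.ndarray
    covariate_names: tuple[str, ...]
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.series.shape[0], dtype=bool)
        if np.any(np.diff(self.durations) < 0):
            raise ValueError("durations must be non-decreasing along the order")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]

    def _region_rows(self, region_mask: np.ndarray) -> np.ndarray:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != self.mask.shape:
            raise ValueError("region mask shape must match")
        if np.any(region_mask & ~self.mask):
            raise ValueError("region extends outside the mask")
        flat_pos = np.cumsum(self.mask.ravel()) - 1
        return flat_pos[region_mask.ravel()]

    def roi_series(self, region_mask: np.ndarray) -> np.ndarray:
        """Standardized pseudo-time series of a region's mean GMV."""
        rows = self._region_rows(region_mask)
        if rows.size == 0:
            raise ValueError("region is empty")
        mean = self.resid_series[rows].mean(axis=0)
        return standardize_series(mean)


def standardize_series(x: np.ndarray) -> np.ndarray:
    """Mean 0 / SD 1 (population SD); constant series raise."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return (x - x.mean()) / sd


def build_pseudo_timeseries(
    dataset: GMVDataset,
    records: Sequence[SubjectRecord],
    covariates: Sequence[str] = ("age", "sex", "tiv"),
) -> PseudoTimeSeries:
    """Sort patients by ascending illness duration (stable, ties broken by
    subject id), regress the covariates out of each voxel's cross-subject
    values, and standardize each voxel series.

    ``dataset`` must contain patients only, rows aligned with ``records``.
    """
    records = list(records)
    if len(records) != dataset.n_subjects:
        raise ValueError("records must align with dataset rows")
    for rec, sid in zip(records, dataset.subject_ids):
        if rec.subject_id != sid:
            raise ValueError("records order must match dataset subject order")
        if rec.group != GROUP_PATIENT or rec.duration_months is None:
            raise ValueError(
                f"{rec.subject_id}: pseudo-time series requires patients "
                "with a known illness duration"
            )
    durations = np.array([r.duration_months for r in records], dtype=float)
    ids = np.array([r.subject_id for r in records])

    cols = []
    for cov in covariates:
        if cov == "sex":
            cols.append(np.array([1.0 if r.sex == "male" else 0.0 for r in records]))
        else:
            cols.append(np.array([float(getattr(r, cov)) for r in records]))
    Z = np.column_stack([np.ones(len(records))] + cols)
    resid = residualize(dataset.data, Z)  # subjects x voxels

    order = np.lexsort((ids, durations))
    resid_series = resid[order].T  # voxels x T
    sd = resid_series.std(axis=1)
    degenerate = sd == 0
    mean = resid_series.mean(axis=1)
    series = np.zeros_like(resid_series)
    ok = ~degenerate
    series[ok] = (resid_series[ok] - mean[ok, None]) / sd[ok, None]
    return PseudoTimeSeries(
        order=order,
        subject_ids=[str(ids[i]) for i in order],
        durations=durations[order],
        series=series,
        resid_series=resid_series,
        mask=dataset.mask,
        affine=dataset.affine,
        covariate_names=tuple(covariates),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# stationarity screening
# ---------------------------------------------------------------------------

def kpss_level_test(series: np.ndarray) -> tuple[float, float]:
    """KPSS level-stationarity test (null: the series is stationary around
    a constant).

    Returns ``(statistic, p)`` with p interpolated from the standard
    critical-value table and clipped to its tabulated band [0.01, 0.10].
    A constant series has statistic 0 (trivially stationary).
    """
    from statsmodels.tsa.stattools import kpss
    from statsmodels.tools.sm_exceptions import InterpolationWarning

    series = np.asarray(series, dtype=float)
    if len(series) < 10:
        raise ValueError("series too short for the KPSS test (need >= 10)")
    if np.ptp(series) == 0:
        return 0.0, 0.10
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        stat, p, *_ = kpss(series, regression="c", nlags="auto")
    return float(stat), float(p)


def _apply_remedy(series: np.ndarray, remedy: str) -> np.ndarray:
    """Transform a 1-D series per the configured stationarity remedy and
    re-standardize (the |GC| cut presumes unit-variance inputs)."""
    if remedy == "difference":
        series = np.diff(series)
    elif remedy == "detrend":
        series = signal.detrend(series, type="linear")
    return standardize_series(series)


# ---------------------------------------------------------------------------
# signed-path-coefficient Granger causality
# ---------------------------------------------------------------------------

def signed_path_gc(x: np.ndarray, y: np.ndarray, order: int = 1) -> float:
    """Signed path coefficient of x -> y: the coefficient on ``x_{t-1}`` in
    the OLS fit of ``y_t`` on an intercept, ``y_{t-1..t-order}`` and
    ``x_{t-1..t-order}``.

    Both series should be standardized so the coefficient is scale-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n <= order + 3:
        raise ValueError("series too short for the requested model order")
    cols = [np.ones(n - order)]
    for k in range(1, order + 1):
        cols.append(y[order - k: n - k])
    for k in range(1, order + 1):
        cols.append(x[order - k: n - k])
    A = np.column_stack(cols)
    target = y[order:]
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("collinear lagged regressors: path coefficient undefined")
    beta, *_ = np.linalg.lstsq(A, target, rcond=None)
    return float(beta[1 + order])  # coefficient on x_{t-1}


def _batched_gc_order1(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Order-1 signed-path coefficients of x -> each row of Y, via batched
    pseudo-inverse of the (T-1) x 3 lagged design."""
    T = len(x)
    y_t = Y[:, 1:]                       # (V, T-1)
    y_lag = Y[:, :-1]                    # (V, T-1)
    x_lag = np.broadcast_to(x[:-1], y_lag.shape)
    ones = np.ones_like(y_lag)
    A = np.stack([ones, y_lag, x_lag], axis=2)  # (V, T-1, 3)
    beta = np.linalg.pinv(A) @ y_t[:, :, None]  # (V, 3, 1)
    return beta[:, 2, 0]


@dataclass
class GCResult:
    """Voxelwise causal map from one seed.

    ``surviving`` voxels pass all three cuts: |z| > z_min, |GC| >
    gc_abs_min and BH-FDR at q on the two-tailed normal p of z.
    """

    gc_map: np.ndarray
    z_map: np.ndarray
    surviving: np.ndarray
    nonstationary: np.ndarray
    degenerate: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    config: CascnConfig
    seed_nonstationary: bool = False

    @property
    def n_nonstationary(self) -> int:
        return int(self.nonstationary.sum())


def seed_to_voxel_gc(
    pts: PseudoTimeSeries,
    seed_series: np.ndarray | None = None,
    seed_region: np.ndarray | None = None,
    config: CascnConfig | None = None,
) -> GCResult:
    """Signed-path GC from a seed series to every in-mask voxel.

    The seed is either an explicit (already ordered) series or a region
    mask whose mean residualized series is extracted from ``pts``.  The
    stationarity screen runs first; with ``report_only`` nonstationary
    voxels are flagged and kept, otherwise seed and voxel series are
    transformed before the causal fit.
    """
    config = config or CascnConfig()
    if seed_series is None:
        if seed_region is None:
            raise ValueError("provide seed_series or seed_region")
        seed = pts.roi_series(seed_region)
    else:
        seed = np.asarray(seed_series, dtype=float)
        if len(seed) != pts.n_timepoints:
            raise ValueError("seed series length must match the ordering")
        seed = standardize_series(seed)

    V = pts.series.shape[0]
    ok = ~pts.degenerate

    # stationarity screen
    nonstationary = np.zeros(V, dtype=bool)
    for v in np.nonzero(ok)[0]:
        _, p = kpss_level_test(pts.series[v])
        nonstationary[v] = p < config.kpss_alpha
    _, seed_p = kpss_level_test(seed)
    seed_nonstationary = bool(seed_p < config.kpss_alpha)

    remedy = config.stationarity_remedy
    if remedy == "report_only":
        seed_used = seed
        series_used = pts.series
    else:
        seed_used = _apply_remedy(seed, remedy)
        series_used = np.zeros(
            (V, len(seed_used)), dtype=float
        )
        for v in np.nonzero(ok)[0]:
            series_used[v] = _apply_remedy(pts.series[v], remedy)

    gc_map = np.full(V, np.nan)
    if config.model_order == 1:
        gc_map[ok] = _batched_gc_order1(seed_used, series_used[ok])
    else:
        for v in np.nonzero(ok)[0]:
            gc_map[v] = signed_path_gc(seed_used, series_used[v], config.model_order)

    mu = float(np.nanmean(gc_map[ok]))
    sd = float(np.nanstd(gc_map[ok]))
    z_map = np.full(V, np.nan)
    if sd > 0:
        z_map[ok] = (gc_map[ok] - mu) / sd

    surviving = np.zeros(V, dtype=bool)
    if sd > 0:
        p = 2 * stats.norm.sf(np.abs(z_map[ok]))
        fdr_ok = fdr_bh(p, config.fdr_q)
        pass_all = (
            (np.abs(z_map[ok]) > config.z_min)
            & (np.abs(gc_map[ok]) > config.gc_abs_min)
            & fdr_ok
        )
        surviving[np.nonzero(ok)[0][pass_all]] = True

    return GCResult(
        gc_map=gc_map, z_map=z_map, surviving=surviving,
        nonstationary=nonstationary, degenerate=pts.degenerate,
        mask=pts.mask, affine=pts.affine, config=config,
        seed_nonstationary=seed_nonstationary,
    )


def surviving_clusters(
    result: GCResult, connectivity: int = 26
) -> pd.DataFrame:
    """Connected components of the surviving voxel set with peak |z| and
    world-mm peak coordinates (columns mirror a causal-effects table:
    peak x/y/z, z value at the peak, cluster size)."""
    from .vbm import _connectivity_structure

    structure = _connectivity_structure(connectivity)
    grid = np.zeros(result.mask.shape, dtype=bool)
    grid[result.mask] = result.surviving
    labels, n = ndimage.label(grid, structure=structure)
    flat_pos = np.cumsum(result.mask.ravel()) - 1
    ijk = np.argwhere(result.mask)
    coords_mm = ijk @ result.affine[:3, :3].T + result.affine[:3, 3]
    rows = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        cols = flat_pos[np.ravel_multi_index(tuple(vox.T), result.mask.shape)]
        zvals = result.z_map[cols]
        peak = int(np.argmax(np.abs(zvals)))
        rows.append({
            "cluster": lab,
            "peak_x_mm": coords_mm[cols[peak]][0],
            "peak_y_mm": coords_mm[cols[peak]][1],
            "peak_z_mm": coords_mm[cols[peak]][2],
            "peak_z_value": float(zvals[peak]),
            "peak_gc": float(result.gc_map[cols[peak]]),
            "size_voxels": len(vox),
        })
    frame = pd.DataFrame(
        rows,
        columns=["cluster", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                 "peak_z_value", "peak_gc", "size_voxels"],
    )
    return frame.sort_values("size_voxels", ascending=False).reset_index(drop=True)
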