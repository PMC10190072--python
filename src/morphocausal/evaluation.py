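"""Operating-characteristic studies of the analysis chain on synthetic
cohorts: family-wise-error calibration of the permutation cluster
correction, recovery of a planted causal hierarchy, and bias of the
signed-path coefficient.

These are the package's own validation experiments; they are what the test
suite and the reproduction script run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascn import CascnConfig, build_pseudo_timeseries, seed_to_voxel_gc, signed_path_gc, standardize_series
from .datasets import GROUP_PATIENT
from .roinet import RoiSpec, roi_gc_matrix
from .simulate import CohortSpec, generate_cohort, planted_hierarchy_spec
from .vbm import DesignMatrix, cluster_correct, qc_exclude, two_sample_t_map
from .datasets import records_to_frame

_SEED_MOD = 2**31


def _child_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(base_seed).generate_state(n) % _SEED_MOD


def null_cluster_fwer(
    n_cohorts: int = 200,
    n_patients: int = 20,
    n_controls: int = 20,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    n_perm: int = 300,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    base_seed: int = 0,
) -> tuple[int, int]:
    """Family-wise error of the permutation cluster correction on null
    cohorts (no planted effects): how often does at least one significant
    cluster appear?  Returns ``(n_false_positive, n_cohorts)``."""
    seeds = _child_seeds(base_seed, n_cohorts)
    hits = 0
    for s in seeds:
        spec = CohortSpec(
            n_patients=n_patients, n_controls=n_controls,
            grid_shape=grid_shape, voxel_size_mm=8.0,
            driver_amplitude=0.0, followers=[], n_excluded_controls=0,
            rng_seed=int(s),
        )
        records, dataset = generate_cohort(spec)
        design = DesignMatrix.from_table(records_to_frame(records))
        tmap = two_sample_t_map(dataset, design)
        result = cluster_correct(
            tmap, dataset, design, voxel_p=voxel_p,
            cluster_alpha=cluster_alpha, n_perm=n_perm, rng_seed=int(s),
        )
        hits += bool(result.clusters)
    return hits, n_cohorts


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 0.0


@dataclass
class RecoveryOutcome:
    """Per-replicate results of the planted-hierarchy recovery study."""

    dice_scores: np.ndarray          # largest VBM cluster vs driver mask
    sign_matches: np.ndarray         # both follower gc signs as planted
    driver_max_out: np.ndarray       # driver ROI attains the max out-degree

    @property
    def dice_rate(self) -> float:
        return float((self.dice_scores > 0.5).mean())

    @property
    def sign_match_rate(self) -> float:
        return float(self.sign_matches.mean())

    @property
    def driver_max_out_rate(self) -> float:
        return float(self.driver_max_out.mean())


def _region_center_mm(region: np.ndarray, affine: np.ndarray) -> tuple:
    ijk = np.argwhere(region).mean(axis=0)
    return tuple(affine[:3, :3] @ ijk + affine[:3, 3])


def planted_hierarchy_recovery(
    n_replicates: int = 100,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    n_perm: int = 200,
    roi_radius_mm: float = 8.0,
    base_seed: int = 0,
) -> RecoveryOutcome:
    """Run the full chain on planted-hierarchy cohorts (driver plus +1/-1
    followers, lag 1, gain 0.5, noise SD 1, 86 patients) and score:

    * Dice overlap of the largest significant VBM cluster with the driver;
    * whether the follower regions' median seed-to-voxel GC signs match
      the planted signs;
    * whether the driver ROI attains the maximum out-degree in the
      three-node ROI network at the planted region centers.
    """
    seeds = _child_seeds(base_seed, n_replicates)
    dices = np.zeros(n_replicates)
    signs = np.zeros(n_replicates, dtype=bool)
    maxout = np.zeros(n_replicates, dtype=bool)
    for i, s in enumerate(seeds):
        spec = planted_hierarchy_spec(
            grid_shape=grid_shape, voxel_size_mm=8.0, rng_seed=int(s))
        records, dataset = generate_cohort(spec)
        records = qc_exclude(records)
        dataset = dataset.select_subjects([r.subject_id for r in records])
        design = DesignMatrix.from_table(records_to_frame(records))
        tmap = two_sample_t_map(dataset, design)
        clusters = cluster_correct(
            tmap, dataset, design, n_perm=n_perm, rng_seed=int(s))
        if clusters.clusters:
            found = np.zeros(spec.grid_shape, dtype=bool)
            found[tuple(clusters.clusters[0].voxels.T)] = True
            dices[i] = dice(found, spec.driver_region)

        patients = [r for r in records if r.group == GROUP_PATIENT]
        pat_ds = dataset.select_subjects([r.subject_id for r in patients])
        pts = build_pseudo_timeseries(pat_ds, patients)
        gc = seed_to_voxel_gc(pts, seed_region=spec.driver_region)
        flat_pos = np.cumsum(spec.mask.ravel()) - 1
        ok = True
        for fol in spec.followers:
            cols = flat_pos[fol.region.ravel()]
            ok &= np.sign(np.median(gc.gc_map[cols])) == fol.sign
        signs[i] = ok

        rois = [RoiSpec("driver", _region_center_mm(spec.driver_region, spec.affine),
                        roi_radius_mm)]
        for j, fol in enumerate(spec.followers):
            rois.append(RoiSpec(f"follower_{j}",
                                _region_center_mm(fol.region, spec.affine),
                                roi_radius_mm))
        net = roi_gc_matrix(pts, rois)
        maxout[i] = net.out_degree[0] == net.out_degree.max()
    return RecoveryOutcome(dice_scores=dices, sign_matches=signs,
                           driver_max_out=maxout)


def gc_coefficient_bias(
    n_replicates: int = 1000,
    n: int = 86,
    coefficient: float = 0.5,
    base_seed: int = 0,
) -> tuple[float, float]:
    """Bias of the signed-path coefficient on ``y_t = c x_{t-1} + e_t``
    with unit-variance white inputs: returns ``(bias, target)`` where the
    target is the standardized planted coefficient ``c / sqrt(1 + c^2)``."""
    rng = np.random.default_rng(base_seed)
    target = coefficient / np.sqrt(1.0 + coefficient**2)
    est = np.empty(n_replicates)
    for i in range(n_replicates):
        x = rng.normal(size=n + 1)
        y = np.empty(n + 1)
        y[0] = rng.normal()
        y[1:] = coefficient * x[:-1] + rng.normal(size=n)
        est[i] = signed_path_gc(standardize_series(x[1:]),
                                standardize_series(y[1:]))
    return float(est.mean() - target), float(target)
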