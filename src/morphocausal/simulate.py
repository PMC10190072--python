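"""Synthetic cohort generator with a planted causal hierarchy.

The generator emulates the statistical structure that the duration-ordered
causal analyses assume: a patient/control cohort whose patients carry a
"driver" region whose gray-matter volume grows with illness duration, plus
"follower" regions whose planted effect is a lag-shifted (in
duration-ordered rank), sign- and gain-scaled copy of the driver effect.
After sorting patients by duration, the noiseless follower series is
exactly ``sign * gain *`` the lag-shifted driver series, so seed-to-voxel
and ROI-to-ROI lagged-regression analyses have a known ground truth.

Covariates (age, sex, total intracranial volume) act additively on every
in-mask voxel, and iid Gaussian noise is added on top.  All sampling is
driven by one ``numpy`` Generator seeded from ``rng_seed``, so a spec is a
complete, reproducible description of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    GMVDataset,
    SubjectRecord,
    GROUP_PATIENT,
    GROUP_CONTROL,
    records_to_frame,
    synthetic_affine,
)


@dataclass
class CovariateModel:
    """Distributions of the nuisance covariates and their additive effects
    on GMV (arbitrary GMV units per covariate unit).

    Defaults reproduce the marginal demographics of a young, predominantly
    female migraine cohort: ages tightly clustered in the early twenties
    within the 17-45 inclusion window, male fractions 18/86 (patients) and
    23/76 (controls), TIV near 1430 cm^3.
    """

    age_mean_patient: float = 21.93
    age_sd_patient: float = 2.25
    age_mean_control: float = 21.62
    age_sd_control: float = 0.97
    age_range: tuple[float, float] = (17.0, 45.0)
    p_male_patient: float = 18.0 / 86.0
    p_male_control: float = 23.0 / 76.0
    tiv_mean_patient: float = 1422.35
    tiv_sd_patient: float = 119.29
    tiv_mean_control: float = 1439.10
    tiv_sd_control: float = 135.95
    bmi_mean_patient: float = 20.61
    bmi_sd_patient: float = 2.40
    bmi_mean_control: float = 20.83
    bmi_sd_control: float = 1.62
    # additive effects on GMV; centering constants are fixed so that the
    # generated effect does not depend on the sampled cohort
    beta_age: float = 0.02
    beta_sex_male: float = 0.2
    beta_tiv: float = 0.002
    age_center: float = 22.0
    tiv_center: float = 1430.0


@dataclass
class FollowerSpec:
    """A planted follower region: its effect is ``sign * gain`` times the
    driver effect of the patient ``lag`` positions earlier in duration
    order."""

    region: np.ndarray
    lag: int = 1
    sign: int = 1
    gain: float = 0.5

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        if self.lag < 1:
            raise ValueError("follower lag must be >= 1")
        if self.sign not in (1, -1):
            raise ValueError("follower sign must be +1 or -1")


def _cube(grid_shape: tuple[int, int, int], center: Sequence[int], half: int = 1) -> np.ndarray:
    out = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(c - half, c + half + 1) for c in center)
    out[sl] = True
    return out


def _default_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Inscribed ball: a crude brain-shaped mask for synthetic grids."""
    center = (np.asarray(grid_shape) - 1) / 2.0
    radius = min(grid_shape) / 2.0 - 0.5
    ijk = np.indices(grid_shape).reshape(3, -1).T
    dist = np.linalg.norm(ijk - center, axis=1)
    return (dist <= radius).reshape(grid_shape)


@dataclass
class CohortSpec:
    """Complete description of a synthetic cohort.

    The driver effect defaults to a ramp: zero below the stage boundary
    (default 60 months) and linear from the boundary up to the maximum
    duration, reaching ``driver_amplitude`` there — long-duration
    hypertrophy with no short-duration group difference.
    """

    n_patients: int = 86
    n_controls: int = 76
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 4.0
    mask: np.ndarray | None = None
    duration_range_months: tuple[float, float] = (6.0, 124.0)
    stage_boundary_months: float = 60.0
    driver_region: np.ndarray | None = None
    driver_amplitude: float = 3.0
    driver_effect_fn: Callable[[np.ndarray], np.ndarray] | None = None
    followers: list[FollowerSpec] = field(default_factory=list)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    baseline_gmv: float = 10.0
    noise_sd: float = 1.0
    n_excluded_controls: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.mask is None:
            self.mask = _default_mask(self.grid_shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid_shape:
            raise ValueError("mask shape must equal grid_shape")
        if self.driver_region is None:
            center = tuple(s // 2 for s in self.grid_shape)
            self.driver_region = _cube(self.grid_shape, center)
        self.driver_region = np.asarray(self.driver_region, dtype=bool)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.duration_range_months[0] < 6.0:
            raise ValueError(
                "duration_range_months[0] must be >= 6 (cohort inclusion "
                "requires at least six months of symptoms)"
            )
        if self.duration_range_months[1] <= self.duration_range_months[0]:
            raise ValueError("duration range must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_excluded_controls >= self.n_controls:
            raise ValueError("n_excluded_controls must be < n_controls")
        if self.n_excluded_controls < 0:
            raise ValueError("n_excluded_controls must be >= 0")
        regions = [("driver", self.driver_region)] + [
            (f"follower[{i}]", f.region) for i, f in enumerate(self.followers)
        ]
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for name, region in regions:
            if region.shape != self.grid_shape:
                raise ValueError(f"{name} region shape must equal grid_shape")
            if np.any(region & ~self.mask):
                raise ValueError(f"planted region {name} extends outside the mask")
            if np.any(region & occupied):
                raise ValueError(f"planted region {name} overlaps another planted region")
            occupied |= region

    # -- effect functions -------------------------------------------------
    def driver_effect(self, duration_months: np.ndarray) -> np.ndarray:
        """Noiseless driver GMV effect as a function of illness duration."""
        if self.driver_effect_fn is not None:
            return np.asarray(self.driver_effect_fn(np.asarray(duration_months, float)), float)
        d = np.asarray(duration_months, dtype=float)
        lo = self.stage_boundary_months
        hi = self.duration_range_months[1]
        ramp = np.clip((d - lo) / (hi - lo), 0.0, None)
        return self.driver_amplitude * ramp

    @property
    def affine(self) -> np.ndarray:
        return synthetic_affine(self.grid_shape, self.voxel_size_mm)


def default_followers(spec_grid: tuple[int, int, int], mask: np.ndarray) -> list[FollowerSpec]:
    """Two cubic follower regions flanking the grid center along x (one
    same-sign, one opposite-sign, both lag 1, gain 0.5), at the largest
    offset that keeps both cubes inside the mask and clear of the driver."""
    center = np.asarray(spec_grid) // 2
    for offset in range(center[0] - 1, 2, -1):  # >= 3 keeps cubes disjoint
        lo, hi = center[0] - offset, center[0] + offset
        if lo - 1 < 0 or hi + 1 >= spec_grid[0]:
            continue
        pos = _cube(spec_grid, (lo, center[1], center[2]))
        neg = _cube(spec_grid, (hi, center[1], center[2]))
        if not np.any(pos & ~mask) and not np.any(neg & ~mask):
            return [
                FollowerSpec(region=pos, lag=1, sign=1, gain=0.5),
                FollowerSpec(region=neg, lag=1, sign=-1, gain=0.5),
            ]
    raise ValueError("grid too small to place follower regions inside the mask")


def planted_hierarchy_spec(**overrides) -> CohortSpec:
    """Convenience constructor: driver cube at the grid center plus the two
    default follower cubes (lag 1, gain 0.5, signs +1/-1)."""
    spec = CohortSpec(**{k: v for k, v in overrides.items() if k != "followers"})
    if "followers" in overrides:
        spec.followers = overrides["followers"]
    else:
        spec.followers = default_followers(spec.grid_shape, spec.mask)
    spec.validate()
    return spec


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    return np.clip(out, lo, hi)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GMVDataset]:
    """Draw one cohort: subject records plus a GMV dataset.

    Patient rows come first (ids ``P001..``), then controls (``C001..``);
    exactly ``spec.n_excluded_controls`` controls carry the QC-exclusion
    flag.  Deterministic under a fixed ``rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    cm = spec.covariate_model
    n_p, n_c = spec.n_patients, spec.n_controls
    n = n_p + n_c

    durations = rng.uniform(*spec.duration_range_months, size=n_p)
    age = np.concatenate([
        _truncated_normal(rng, cm.age_mean_patient, cm.age_sd_patient, *cm.age_range, size=n_p),
        _truncated_normal(rng, cm.age_mean_control, cm.age_sd_control, *cm.age_range, size=n_c),
    ])
    is_male = np.concatenate([
        rng.random(n_p) < cm.p_male_patient,
        rng.random(n_c) < cm.p_male_control,
    ])
    tiv = np.concatenate([
        rng.normal(cm.tiv_mean_patient, cm.tiv_sd_patient, size=n_p),
        rng.normal(cm.tiv_mean_control, cm.tiv_sd_control, size=n_c),
    ])
    bmi = np.concatenate([
        rng.normal(cm.bmi_mean_patient, cm.bmi_sd_patient, size=n_p),
        rng.normal(cm.bmi_mean_control, cm.bmi_sd_control, size=n_c),
    ])
    migraine_days = np.clip(rng.normal(5.87, 5.21, size=n_p), 1.0, 30.0)
    vas = np.clip(rng.normal(5.81, 1.80, size=n_p), 0.0, 10.0)
    sas = np.clip(rng.normal(45.19, 8.74, size=n_p), 20.0, 80.0)
    sds = np.clip(rng.normal(45.22, 10.47, size=n_p), 20.0, 80.0)
    excluded = rng.choice(n_c, size=spec.n_excluded_controls, replace=False)

    records: list[SubjectRecord] = []
    for i in range(n_p):
        records.append(SubjectRecord(
            subject_id=f"P{i + 1:03d}", group=GROUP_PATIENT,
            age=float(age[i]), sex="male" if is_male[i] else "female",
            tiv=float(tiv[i]), bmi=float(bmi[i]),
            duration_months=float(durations[i]),
            monthly_migraine_days=float(migraine_days[i]),
            headache_intensity_vas=float(vas[i]),
            sas=float(sas[i]), sds=float(sds[i]),
        ))
    for j in range(n_c):
        records.append(SubjectRecord(
            subject_id=f"C{j + 1:03d}", group=GROUP_CONTROL,
            age=float(age[n_p + j]), sex="male" if is_male[n_p + j] else "female",
            tiv=float(tiv[n_p + j]), bmi=float(bmi[n_p + j]),
            qc_excluded=bool(j in excluded),
        ))

    # --- maps -------------------------------------------------------------
    n_vox = int(spec.mask.sum())
    data = np.full((n, n_vox), spec.baseline_gmv, dtype=float)
    covariate_effect = (
        cm.beta_age * (age - cm.age_center)
        + cm.beta_sex_male * is_male.astype(float)
        + cm.beta_tiv * (tiv - cm.tiv_center)
    )
    data += covariate_effect[:, None]

    # planted effects (patients only), defined in duration-ordered rank
    dummy = GMVDataset(
        subject_ids=[r.subject_id for r in records],
        data=data, mask=spec.mask, affine=spec.affine,
    )
    driver_cols = dummy.region_columns(spec.driver_region)
    drv = spec.driver_effect(durations)  # per patient, id order
    order = np.argsort(durations, kind="stable")  # ties fall back to id order
    drv_ordered = drv[order]
    data[np.ix_(np.arange(n_p), driver_cols)] += drv[:, None]
    for fol in spec.followers:
        fol_cols = dummy.region_columns(fol.region)
        eff_ordered = np.zeros(n_p)
        eff_ordered[fol.lag:] = fol.sign * fol.gain * drv_ordered[: n_p - fol.lag]
        eff = np.empty(n_p)
        eff[order] = eff_ordered
        data[np.ix_(np.arange(n_p), fol_cols)] += eff[:, None]

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    dataset = GMVDataset(
        subject_ids=[r.subject_id for r in records],
        data=data, mask=spec.mask, affine=spec.affine,
    )
    return records, dataset


# ---------------------------------------------------------------------------
# demographics summary
# ---------------------------------------------------------------------------

_CONTINUOUS_BOTH = [("Age (years)", "age"), ("BMI", "bmi"), ("TIV", "tiv")]
_PATIENT_ONLY = [
    ("Duration (months)", "duration_months"),
    ("Monthly migraine days", "monthly_migraine_days"),
    ("Headache intensity (VAS)", "headache_intensity_vas"),
    ("SAS", "sas"),
    ("SDS", "sds"),
]


def demographics_table(records: Sequence[SubjectRecord] | pd.DataFrame) -> pd.DataFrame:
    """Group-wise demographics summary with between-group tests.

    Continuous variables are summarized as mean and SD per group and
    compared with a pooled-variance two-sample t test; sex with a Pearson
    chi-square on the 2x2 male/female table.  Duration and clinical scores
    are summarized for patients only.  ddof=1 SDs throughout.
    """
    from .vbm import chisq_from_counts, pooled_t_from_summary
    from scipy import stats

    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    pat = frame[frame["group"] == GROUP_PATIENT]
    con = frame[frame["group"] == GROUP_CONTROL]
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("need at least 2 subjects per group")

    rows = []
    pm = int((pat["sex"] == "male").sum())
    pf = len(pat) - pm
    cm_ = int((con["sex"] == "male").sum())
    cf = len(con) - cm_
    try:
        chi2 = chisq_from_counts(np.array([[pm, pf], [cm_, cf]]))
        chi2_p = float(stats.chi2.sf(chi2, df=1))
    except ValueError:  # a zero marginal (e.g. single-sex cohort)
        chi2, chi2_p = np.nan, np.nan
    rows.append({
        "variable": "Sex (male/female)",
        "patients": f"{pm}/{pf}", "controls": f"{cm_}/{cf}",
        "patient_mean": np.nan, "patient_sd": np.nan,
        "control_mean": np.nan, "control_sd": np.nan,
        "statistic": chi2, "test": "chi2", "p_value": chi2_p,
    })
    for label, col in _CONTINUOUS_BOTH:
        m1, s1 = float(pat[col].mean()), float(pat[col].std(ddof=1))
        m2, s2 = float(con[col].mean()), float(con[col].std(ddof=1))
        try:
            t = pooled_t_from_summary(m1, s1, len(pat), m2, s2, len(con))
            df = len(pat) + len(con) - 2
            p = float(2 * stats.t.sf(abs(t), df))
        except ValueError:  # degenerate: both SDs zero, equal means
            t, p = np.nan, np.nan
        rows.append({
            "variable": label,
            "patients": f"{m1:.2f} ± {s1:.2f}",
            "controls": f"{m2:.2f} ± {s2:.2f}",
            "patient_mean": m1, "patient_sd": s1,
            "control_mean": m2, "control_sd": s2,
            "statistic": t, "test": "t", "p_value": p,
        })
    for label, col in _PATIENT_ONLY:
        vals = pat[col].dropna()
        if vals.empty:
            continue
        m1, s1 = float(vals.mean()), float(vals.std(ddof=1))
        rows.append({
            "variable": label,
            "patients": f"{m1:.2f} ± {s1:.2f}", "controls": "",
            "patient_mean": m1, "patient_sd": s1,
            "control_mean": np.nan, "control_sd": np.nan,
            "statistic": np.nan, "test": "", "p_value": np.nan,
        })
    return pd.DataFrame(rows)
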