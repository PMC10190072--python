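"""Core in-memory containers for gray-matter-volume (GMV) analyses.

A :class:`GMVDataset` holds one row per subject of in-mask voxel values
together with the 3-D mask and the voxel-to-mm affine, so every downstream
statistic can report world (mm) coordinates.  Subject metadata travels as a
:class:`pandas.DataFrame` with the columns in :data:`SUBJECT_COLUMNS`;
:class:`SubjectRecord` is the row-level construction helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of the subject table (TSV on disk).
SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "tiv",
    "bmi",
    "duration_months",
    "monthly_migraine_days",
    "headache_intensity_vas",
    "sas",
    "sds",
    "qc_excluded",
]

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"


@dataclass
class SubjectRecord:
    """One cohort-table row.

    ``duration_months`` and the clinical scores are present iff the subject
    is a patient; ``sex`` is coded ``"male"``/``"female"``.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    tiv: float
    bmi: float = np.nan
    duration_months: float | None = None
    monthly_migraine_days: float | None = None
    headache_intensity_vas: float | None = None
    sas: float | None = None
    sds: float | None = None
    qc_excluded: bool = False

    def __post_init__(self) -> None:
        if self.group not in (GROUP_PATIENT, GROUP_CONTROL):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        is_patient = self.group == GROUP_PATIENT
        has_duration = self.duration_months is not None and not (
            isinstance(self.duration_months, float) and np.isnan(self.duration_months)
        )
        if is_patient != has_duration:
            raise ValueError(
                "duration_months must be present for patients and absent for controls"
            )
        if self.headache_intensity_vas is not None and not np.isnan(
            float(self.headache_intensity_vas)
        ):
            if not 0.0 <= float(self.headache_intensity_vas) <= 10.0:
                raise ValueError("headache_intensity_vas must lie in [0, 10]")


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Assemble subject records into the canonical cohort DataFrame."""
    rows = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    frame["qc_excluded"] = frame["qc_excluded"].astype(bool)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Inverse of :func:`records_to_frame` (NaN optional fields become None)."""
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in SUBJECT_COLUMNS:
            value = row[col]
            if col in ("subject_id", "group", "sex"):
                kwargs[col] = str(value)
            elif col == "qc_excluded":
                kwargs[col] = bool(value)
            else:
                kwargs[col] = None if pd.isna(value) else float(value)
        records.append(SubjectRecord(**kwargs))
    return records


@dataclass
class GMVDataset:
    """Subjects x in-mask-voxels GMV matrix with grid geometry.

    Parameters
    ----------
    subject_ids
        Unique identifiers; row order defines subject order everywhere
        downstream.
    data
        ``(n_subjects, n_voxels)`` array of GMV values at the ``True``
        positions of ``mask`` in C order.
    mask
        Boolean 3-D brain mask.
    affine
        4x4 voxel-index -> mm mapping.
    """

    subject_ids: list[str]
    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (subjects x voxels)")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} voxels"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length must match data rows")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_indices(self) -> np.ndarray:
        """``(n_voxels, 3)`` integer grid indices of the in-mask voxels."""
        return np.argwhere(self.mask)

    def voxel_coordinates_mm(self) -> np.ndarray:
        """``(n_voxels, 3)`` world-mm coordinates of the in-mask voxel centers."""
        ijk = self.voxel_indices()
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3-D grid."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError("values must have one entry per in-mask voxel")
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    def region_columns(self, region_mask: np.ndarray) -> np.ndarray:
        """Column indices (into ``data``) of a 3-D boolean region ⊆ mask."""
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != self.mask.shape:
            raise ValueError("region mask shape must match dataset mask")
        if np.any(region_mask & ~self.mask):
            raise ValueError("region extends outside the dataset mask")
        flat_pos = np.cumsum(self.mask.ravel()) - 1
        return flat_pos[region_mask.ravel()]

    def select_subjects(self, ids: Sequence[str]) -> "GMVDataset":
        """Row subset in the given id order."""
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"unknown subject id {exc.args[0]!r}") from None
        return GMVDataset(
            subject_ids=list(ids),
            data=self.data[rows],
            mask=self.mask,
            affine=self.affine,
        )


def synthetic_affine(grid_shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """MNI-like affine for a synthetic grid: isotropic voxels, origin at the
    grid center so world coordinates straddle zero like MNI space."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size_mm
    affine[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * voxel_size_mm
    return affine
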