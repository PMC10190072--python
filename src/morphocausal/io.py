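"""NIfTI and table input/output.

GMV maps travel as one NIfTI image per subject plus a shared mask image;
subject tables as TSV with the canonical column set.  Geometry (shape and
affine) must agree across all images of a dataset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datasets import GMVDataset, SubjectRecord, SUBJECT_COLUMNS, frame_to_records, records_to_frame

AFFINE_ATOL = 1e-4


def write_gmv_dataset(dataset: GMVDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one ``<subject_id>_gmv.nii.gz``-style (uncompressed ``.nii``)
    image per subject plus ``mask.nii``; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mask_img = nib.Nifti1Image(dataset.mask.astype(np.uint8), dataset.affine)
    mask_path = out_dir / "mask.nii"
    nib.save(mask_img, mask_path)
    paths["__mask__"] = mask_path
    for i, sid in enumerate(dataset.subject_ids):
        grid = np.zeros(dataset.mask.shape, dtype=np.float64)
        grid[dataset.mask] = dataset.data[i]
        img = nib.Nifti1Image(grid, dataset.affine)
        path = out_dir / f"{sid}_gmv.nii"
        nib.save(img, path)
        paths[sid] = path
    return paths


def read_gmv_dataset(
    paths: dict[str, str | Path] | Sequence[tuple[str, str | Path]],
    mask_path: str | Path,
) -> GMVDataset:
    """Assemble a dataset from per-subject NIfTI images and a mask.

    ``paths`` maps subject id -> image path; row order follows the mapping
    order.  All images must share the mask's grid shape and affine (within
    a small tolerance), else the offending file is named.
    """
    items = list(paths.items()) if isinstance(paths, dict) else list(paths)
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj).astype(bool)
    affine = mask_img.affine
    rows = []
    ids = []
    for sid, path in items:
        img = nib.load(str(path))
        if img.shape != mask.shape:
            raise ValueError(
                f"{path}: shape {img.shape} does not match mask shape {mask.shape}"
            )
        if not np.allclose(img.affine, affine, atol=AFFINE_ATOL):
            raise ValueError(f"{path}: affine does not match the mask affine")
        grid = np.asarray(img.dataobj, dtype=float)
        rows.append(grid[mask])
        ids.append(sid)
    return GMVDataset(subject_ids=ids, data=np.array(rows), mask=mask, affine=affine)


def write_statmap_nifti(values, mask, affine, path) -> None:
    """Scatter a per-voxel vector onto the grid and save as NIfTI."""
    grid = np.zeros(mask.shape, dtype=np.float64)
    grid[mask] = np.nan_to_num(np.asarray(values, dtype=float))
    nib.save(nib.Nifti1Image(grid, affine), str(path))


def write_subject_table(records: Sequence[SubjectRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(SUBJECT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return frame_to_records(frame)
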