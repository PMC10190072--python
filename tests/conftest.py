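import numpy as np
import pytest

import morphocausal as mc


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_spec():
    """Planted-hierarchy cohort on a reduced 16^3 grid (driver cube at the
    grid center, +1 and -1 follower cubes, lag 1, gain 0.5, noise SD 1)."""
    return mc.planted_hierarchy_spec(
        grid_shape=(16, 16, 16), voxel_size_mm=8.0, rng_seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    records, dataset = mc.generate_cohort(small_spec)
    return records, dataset


@pytest.fixture(scope="session")
def patient_pts(small_spec, small_cohort):
    """Pseudo-time series of the patients of the small cohort."""
    records, dataset = small_cohort
    patients = [r for r in records if r.group == "patient"]
    pat_ds = dataset.select_subjects([r.subject_id for r in patients])
    return mc.build_pseudo_timeseries(pat_ds, patients)


def tiny_dataset(rng, n_subjects=12, shape=(3, 3, 3), n_mask=5):
    """A dataset with a handful of in-mask voxels for oracle comparisons."""
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[:n_mask] = True
    data = rng.normal(size=(n_subjects, n_mask))
    affine = mc.synthetic_affine(shape, 2.0)
    ids = [f"S{i:02d}" for i in range(n_subjects)]
    return mc.GMVDataset(subject_ids=ids, data=data, mask=mask, affine=affine)
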