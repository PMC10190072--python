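"""Voxel-based morphometry on a synthetic cohort: covariate-adjusted group
t map, permutation cluster correction, duration-stage ANCOVA, and the
duration partial correlation.

Expected outcome: one significant cluster over the planted driver region,
carried by the long-duration patients."""

import numpy as np

import morphocausal as mc

spec = mc.planted_hierarchy_spec(grid_shape=(16, 16, 16), voxel_size_mm=8.0,
                                 rng_seed=1)
records, dataset = mc.generate_cohort(spec)
records = mc.qc_exclude(records)
dataset = dataset.select_subjects([r.subject_id for r in records])
table = mc.records_to_frame(records)

design = mc.DesignMatrix.from_table(table)  # intercept, group, age, sex, tiv
tmap = mc.two_sample_t_map(dataset, design)
clusters = mc.cluster_correct(tmap, dataset, design, voxel_p=0.001,
                              cluster_alpha=0.05, n_perm=500, rng_seed=1)
print("significant clusters (patient > control where t > 0):")
print(clusters.to_table().to_string(index=False))

# duration stages: boundary at 60 months, boundary itself counts as long
split = mc.stage_split(records, boundary_months=60.0)
print(f"\nstage split: {split.n_short} short (< 60 mo), {split.n_long} long")

# seed-cluster mean GMV across the three subgroups, covariate-adjusted
seed_region = np.zeros(dataset.mask.shape, dtype=bool)
seed_region[tuple(clusters.clusters[0].voxels.T)] = True
roi = mc.extract_roi_mean(dataset, seed_region)
labels = np.array([
    ("short" if r.subject_id in set(split.short_ids) else "long")
    if r.group == "patient" else "control" for r in records])
covs = design.matrix[:, 2:]
anc = mc.roi_ancova(roi, labels, covs)
print(f"\nANCOVA across control/short/long: F = {anc.f_statistic:.3f}, "
      f"p = {anc.p_value:.2e}")
print(anc.pairwise.to_string(index=False))
# The long-duration contrasts dominate by orders of magnitude: the planted
# effect is zero below the 60-month boundary, so the disease signal is
# carried almost entirely by the long-duration subgroup.  (The ROI was
# selected from the same comparison, so small circular-selection effects in
# the weaker contrasts are expected.)

pat = table["group"] == "patient"
r, p = mc.partial_correlation(roi[pat.to_numpy()],
                              table.loc[pat, "duration_months"].to_numpy(),
                              covs[pat.to_numpy()])
print(f"\npartial correlation of cluster GMV with duration (patients): "
      f"r = {r:.3f}, p = {p:.2e}")
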