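"""Causal structural covariance: order patients by illness duration to
form a pseudo-time series, screen stationarity, and map signed-path
Granger causality from the driver seed to every voxel.

A positive GC value at a voxel means its GMV changes in the same direction
as the seed did one duration-ordered step earlier; negative, the opposite
direction."""

import numpy as np

import morphocausal as mc

spec = mc.planted_hierarchy_spec(grid_shape=(16, 16, 16), voxel_size_mm=8.0,
                                 rng_seed=1)
records, dataset = mc.generate_cohort(spec)
patients = [r for r in records if r.group == "patient"]
pat = dataset.select_subjects([r.subject_id for r in patients])

pts = mc.build_pseudo_timeseries(pat, patients)  # sorts, residualizes, standardizes
print(f"pseudo-time series: {pts.n_timepoints} patients ordered by duration "
      f"({pts.durations[0]:.0f} to {pts.durations[-1]:.0f} months)")

stat, p = mc.kpss_level_test(pts.roi_series(spec.driver_region))
print(f"KPSS on the seed series: statistic = {stat:.3f}, p = {p:.3f} "
      "(a trending disease signal is nonstationary by design)")

result = mc.seed_to_voxel_gc(pts, seed_region=spec.driver_region,
                             config=mc.CascnConfig())
print(f"\nsurviving voxels (|z| > 2.3, |GC| > 0.16, FDR q = 0.05): "
      f"{result.surviving.sum()}")
print(f"nonstationary voxel series flagged by KPSS: {result.n_nonstationary}")
for i, fol in enumerate(spec.followers):
    flat = np.cumsum(spec.mask.ravel()) - 1
    cols = flat[fol.region.ravel()]
    print(f"  follower {i} (planted sign {fol.sign:+d}, lag {fol.lag}): "
          f"median GC = {np.median(result.gc_map[cols]):+.3f}")
# The recovered GC signs match the planted follower signs: the driver's
# change precedes same-direction (+) and opposite-direction (-) changes.

print("\nsurviving clusters (peak coordinates in mm):")
print(mc.surviving_clusters(result).to_string(index=False))
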