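# Methods

## Scope and data model

The package operates strictly downstream of MRI preprocessing: its input
is a set of per-subject gray-matter-volume (GMV) maps on a common grid
(NIfTI), a shared brain mask, and a subject table (group, age, sex, total
intracranial volume, illness duration, clinical scores).  Segmentation,
normalization and smoothing are assumed done; the synthetic generator
stands in for scanner plus preprocessing when no real data are at hand.
All analyses run on the `GMVDataset` container (subjects × in-mask
voxels, with the mask and the voxel-to-mm affine), and every reported
coordinate is world mm through that affine; voxel indices are never
exposed in outputs.

## Synthetic cohorts

`simulate.generate_cohort` draws a patient/control cohort whose patients
carry a planted causal hierarchy:

* **Driver region** — a voxel set whose GMV gains
  `driver_effect(duration)` on top of baseline.  The default effect is a
  ramp: zero below the 60-month stage boundary, linear from the boundary
  to the maximum duration, reaching `driver_amplitude` (default 3.0, in
  units of the noise SD) there.  This shape produces long-duration
  hypertrophy with no short-duration group difference, the pattern the
  stage-split analysis is designed to detect.
* **Follower regions** — each has a lag (ordered-subject steps, ≥ 1), a
  sign (±1) and a gain.  The follower effect of the patient at
  duration-ordered rank *r* is `sign × gain × driver_effect` of the
  patient at rank *r − lag* (zero when *r − lag* < 0), so after ordering,
  the noiseless follower series is exactly a lag-shifted, sign/gain-scaled
  copy of the driver series.  Defaults: two followers, lag 1, gain 0.5,
  signs +1 and −1.
* **Covariates** — age, sex and TIV are drawn per group from
  distributions matching a young, predominantly female migraine cohort
  (ages ≈ 22 ± 2 within a 17–45 window, male fractions 18/86 and 23/76,
  TIV ≈ 1430 ± 130), and act additively on every in-mask voxel with fixed
  small coefficients.  Clinical scores (monthly migraine days, VAS
  headache intensity, anxiety/depression scales) are drawn for patients
  only and carry no planted relation to the imaging signal.
* **Illness duration** — Uniform(6, 124) months, giving mean 65 and SD 34
  with roughly balanced stage subgroups around the 60-month boundary.
  The lower limit 6 reflects the cohort inclusion criterion; durations
  below it are rejected everywhere.
* **Noise** — iid Gaussian, SD 1.0 by default, added after all planted
  effects; exactly `n_excluded_controls` controls (default 3 of 76) are
  flagged for QC exclusion.

Cohort defaults are 86 patients / 76 controls.  The default grid is 24³
with an inscribed-ball mask; the validation studies and tests run on 16³
(≈ 1700 in-mask voxels, 8 mm voxels), a desk-scale choice — every method
is resolution-agnostic, and the acceptance properties are statistical,
not anatomical.  What the generator does **not** emulate: spatial noise
correlation from smoothing, anatomical tissue boundaries, registration
error, site/scanner effects, or any nonlinear covariate influence.
Passing tests therefore demonstrate the estimators' statistical
correctness and calibration under the stated model, not robustness to
real-scanner artifacts.

## VBM

Per voxel, OLS of GMV on `[intercept, group, age, sex, TIV]` (group
patient = 1, sex male = 1), reported as the t of the group coefficient
with df = n − p.  Voxels whose residual variance is zero up to round-off
(relative tolerance 1e-10 of the response scale) are flagged degenerate,
get a NaN statistic, and are excluded from thresholding — this is how
noiseless fixtures behave sanely.  Rank-deficient designs are rejected
with the collinear columns named.

**Cluster correction.**  Cluster-level family-wise error is controlled by
permutation rather than Gaussian-random-field theory: GRF needs a
smoothness estimate that is meaningless on unsmoothed synthetic grids,
while the permutation test targets the same inferential quantity
(cluster-level FWE) assumption-free and is exactly testable by
Monte-Carlo.  The forming threshold is the two-tailed voxel p < 0.001
quantile of t(df); components of |t| above it use 26-connectivity
(configurable to 6).  The null distribution of the maximum cluster size
is built by Freedman–Lane permutation: the covariate-only model is
fitted, its residuals are permuted over subjects, the fitted covariate
part is added back, and the full model is refitted.  A cluster is
significant when its exact permutation p, (1 + #{null ≥ size})/(B + 1),
is ≤ α — the plus-one convention of exact permutation tests, equivalent
to the "size exceeds the (1 − α) null quantile" rule up to the inclusion
of the identity permutation, and valid by construction.  Because the max
cluster size is a small integer under the null, the achievable level is
discrete and the test runs conservative (realized FWER ≈ 0.01–0.03 at
nominal 0.05 in the calibration study); it stays within the binomial 95%
band checked by the acceptance suite.

**Stage analysis.**  Patients split at 60 months (boundary inclusive to
the long stage).  The ROI mean of a significant cluster is compared
across control/short/long with an ANCOVA (extra-sum-of-squares F for the
group factor after covariate adjustment — Type III-equivalent for a
single factor) and pairwise covariate-adjusted t tests with Bonferroni ×3
(capped at 1).  The subgroup post-hoc contrasts are covariate-adjusted
throughout; whether the adjustment belongs in the post-hoc stage is a
genuinely open design point, resolved here in favor of one consistent
model.  Associations with duration and symptom scores use partial
correlation: residualize both variables on `[1, covariates]`, Pearson r
of residuals, p from the t transform at df = n − k − 2.

**Demographics.**  The group table uses the pooled-variance two-sample t
for continuous rows and the Pearson chi-square without continuity
correction for sex — the conventions that reproduce printed cohort-table
statistics from their cell values.

## SCN

Two models are provided because "covariance alteration relative to
controls" is ambiguous between them: a within-group map (t of the seed
regressor among patients) and a seed×group interaction map (slope
difference between groups).  Both are plain OLS per voxel; the default
report uses the within-patient map, and the two are labeled distinctly.
FDR (Benjamini–Hochberg step-up, implemented directly and cross-checked
against brute force and statsmodels) is applied over in-mask,
non-degenerate voxels only.

## CaSCN

`build_pseudo_timeseries` sorts patients by ascending duration — a stable
sort with ties broken by subject id, so repeated runs agree — then
regresses age/sex/TIV out of each voxel's cross-subject values by OLS and
standardizes each voxel series to mean 0 / SD 1.  Covariate handling is
pre-residualization of every series rather than per-regression exogenous
terms; by the Frisch–Waugh argument the lagged-seed coefficient agrees
between the two routes (asserted on small instances in the tests), and
one documented model keeps every downstream series on the same footing.

The **signed-path coefficient** of x → y is the coefficient on x_{t−1} in
OLS of y_t on `[1, y_{t−1..t−m}, x_{t−1..t−m}]`, model order m = 1 by
default (configurable).  On standardized series the coefficient is
scale-free, which is the only reading under which a fixed |GC| > 0.16 cut
is meaningful; the cut is applied after covariate residualization.

The voxelwise map z-scores the GC values across in-mask voxels (mean 0,
SD 1 by construction) and keeps voxels passing all three of: |z| > 2.3,
|GC| > 0.16, and BH-FDR at q = 0.05 on the two-tailed normal p of z.
Thresholding is conjunctive and monotone: tightening any cut never grows
the surviving set.

**Stationarity.**  A KPSS level test (statsmodels implementation;
p interpolated within the tabulated [0.01, 0.10] band; constant series
defined as statistic 0) screens every voxel series and the seed before
the causal fit.  Default policy is `report_only` — flag and keep — with
`difference` and `detrend` available; the transformed series are
re-standardized before the fit.  The default is deliberate: a trending
disease signal is nonstationary *by design*, and differencing it away
would remove precisely the progression signal of interest, so the screen
reports rather than remedies unless the user opts in.

## ROI network

Sphere ROIs (default radius 8 mm) are built in world space: a voxel
belongs to the sphere when its **center** lies within the radius
(inclusive) of the ROI center — an explicit rasterization rule verified
against exhaustive enumeration.  ROI series are means of the
covariate-residualized voxel series, re-standardized.  For every ordered
pair the signed-path GC is estimated; the binary network keeps edges with
|GC| strictly above 0.16 (no z cut at this stage, mirroring the voxelwise
analysis asymmetry), and nodes are scored by out-degree, in-degree and
their sum.  "Transition" nodes are flagged by the interpretive rule
|in − out| ≤ 1; no numeric convention exists for "balanced", so the rule
is explicit and exposed.  Degree identities (Σin = Σout = edge count;
degree = in + out) are property-tested on random matrices.

## Pipeline and determinism

`run_pipeline` chains simulate → QC → demographics → VBM → stage/ROI
statistics → SCN → CaSCN → ROI network.  The CaSCN seed defaults to the
largest significant VBM cluster; ROI centers come from the seed peak plus
the surviving causal-cluster peaks.  All thresholds (0.001, 0.05, 2.3,
0.16, 60 months) live in one `PipelineConfig` with those defaults.  Every
report carries a SHA-256 hash of the config and the pseudo-time caveat
(ordering along duration is not measured time), and reruns with the same
config are byte-identical.  All randomness — cohort draws and permutation
nulls — flows through explicit integer seeds.

## Validation studies (`evaluation.py`)

* **Null calibration** — 200 cohorts with no planted effects (16³ grid,
  20 + 20 subjects, 300 permutations): the fraction with any significant
  cluster must lie in the binomial 95% band around 0.05.
* **Planted-hierarchy recovery** — 100 cohorts at the generator defaults
  (86 patients, driver amplitude 3, followers lag 1 / gain 0.5 / signs
  ±1, noise SD 1): the largest VBM cluster overlaps the driver at
  Dice > 0.5 in ≥ 90% of replicates; the follower regions' median GC
  signs match the planted signs; the driver ROI attains the maximum
  out-degree (ties included) in a clear majority of replicates.
* **Coefficient bias** — on y_t = 0.5 x_{t−1} + e at n = 86 over 1000
  replicates, the mean signed-path estimate is within 0.05 of the
  standardized planted coefficient 0.5/√1.25.

These problem sizes are the package's validation conditions; they were
chosen once as desk-scale analogues of a realistic cohort and are not
tuned per run.

## Known limitations

* Pseudo-time causality is ordering along duration, not longitudinal
  change; the caveat is stamped on every report.
* The permutation cluster test is conservative at small null cluster
  sizes (discreteness); cluster *mass* would be less discrete but is not
  the statistic specified for this chain.
* The z-scored GC map normalizes over whatever signal is present, so the
  surviving set shrinks when planted (or true) effects occupy a large
  fraction of the mask — visible on very small grids.
* The ROI network applies no stationarity remedy of its own and inherits
  trend-driven edges between followers; the driver's out-degree dominance
  is the robust read-out, individual follower-to-follower edges are not.
* Only degree metrics are computed on the network; richer graph measures
  are out of scope.
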