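"""Voxelwise GLM, demographic statistics, stage split, ROI statistics."""

import numpy as np
import pytest
from scipy import stats

import morphocausal as mc
from morphocausal.vbm import DesignMatrix
from conftest import tiny_dataset


def _design_from_arrays(group, covs):
    cols = [np.ones(len(group)), np.asarray(group, float)]
    names = ["intercept", "group"]
    for i in range(covs.shape[1]):
        cols.append(covs[:, i])
        names.append(f"cov{i}")
    return DesignMatrix(np.column_stack(cols), names)


class TestTwoSampleTMap:
    def test_matches_per_voxel_statsmodels_ols(self, rng):
        """Vectorized t equals an independent single-voxel regression."""
        import statsmodels.api as sm

        ds = tiny_dataset(rng, n_subjects=12, n_mask=5)
        group = (np.arange(12) < 6).astype(float)
        covs = rng.normal(size=(12, 2))
        design = _design_from_arrays(group, covs)
        tmap = mc.two_sample_t_map(ds, design)
        for v in range(5):
            fit = sm.OLS(ds.data[:, v], design.matrix).fit()
            assert tmap.values[v] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert tmap.df == int(fit.df_resid)

    def test_no_covariates_equals_pooled_two_sample_t(self, rng):
        ds = tiny_dataset(rng, n_subjects=20, n_mask=5)
        group = (np.arange(20) < 10).astype(float)
        design = _design_from_arrays(group, np.empty((20, 0)))
        tmap = mc.two_sample_t_map(ds, design)
        for v in range(5):
            t_ref = stats.ttest_ind(
                ds.data[:10, v], ds.data[10:, v], equal_var=True
            ).statistic
            assert tmap.values[v] == pytest.approx(-t_ref, abs=1e-10) or \
                tmap.values[v] == pytest.approx(t_ref, abs=1e-10)
            # group coded 1 for the first half: sign must match group1-group2
            t_sum = mc.pooled_t_from_summary(
                ds.data[:10, v].mean(), ds.data[:10, v].std(ddof=1), 10,
                ds.data[10:, v].mean(), ds.data[10:, v].std(ddof=1), 10,
            )
            assert tmap.values[v] == pytest.approx(t_sum, abs=1e-10)

    def test_null_t_values_follow_t_distribution(self, rng):
        """Two groups from one distribution: pooled voxel t values pass a
        KS test against t(df) at the 1% level."""
        n, V = 30, 4000
        mask = np.ones((20, 20, 10), dtype=bool)
        data = rng.normal(size=(n, V))
        ds = mc.GMVDataset([f"S{i}" for i in range(n)], data, mask,
                           mc.synthetic_affine((20, 20, 10), 2.0))
        group = (np.arange(n) < 15).astype(float)
        design = _design_from_arrays(group, np.empty((n, 0)))
        tmap = mc.two_sample_t_map(ds, design)
        p = stats.kstest(tmap.values, stats.t(df=tmap.df).cdf).pvalue
        assert p > 0.01

    def test_invariant_to_joint_subject_reordering(self, rng):
        ds = tiny_dataset(rng, n_subjects=14, n_mask=5)
        group = (np.arange(14) < 7).astype(float)
        covs = rng.normal(size=(14, 2))
        design = _design_from_arrays(group, covs)
        t1 = mc.two_sample_t_map(ds, design).values
        perm = rng.permutation(14)
        ds2 = mc.GMVDataset([ds.subject_ids[i] for i in perm], ds.data[perm],
                            ds.mask, ds.affine)
        design2 = _design_from_arrays(group[perm], covs[perm])
        t2 = mc.two_sample_t_map(ds2, design2).values
        np.testing.assert_allclose(t1, t2, atol=1e-10)

    def test_invariant_to_covariate_rescaling(self, rng):
        ds = tiny_dataset(rng, n_subjects=16, n_mask=5)
        group = (np.arange(16) < 8).astype(float)
        covs = rng.normal(size=(16, 2))
        t1 = mc.two_sample_t_map(ds, _design_from_arrays(group, covs)).values
        t2 = mc.two_sample_t_map(
            ds, _design_from_arrays(group, covs * np.array([100.0, 1e-3]) + 7.0)
        ).values
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_degenerate_voxel_flagged(self, rng):
        ds = tiny_dataset(rng, n_subjects=12, n_mask=5)
        ds.data[:, 2] = 3.14  # constant voxel: zero residual variance
        group = (np.arange(12) < 6).astype(float)
        design = _design_from_arrays(group, np.empty((12, 0)))
        tmap = mc.two_sample_t_map(ds, design)
        assert tmap.degenerate[2]
        assert np.isnan(tmap.values[2])
        assert not tmap.degenerate[[0, 1, 3, 4]].any()

    def test_rank_deficient_design_names_columns(self, rng):
        ds = tiny_dataset(rng, n_subjects=12, n_mask=5)
        group = (np.arange(12) < 6).astype(float)
        mat = np.column_stack([np.ones(12), group, group * 2.0])
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(mat, ["intercept", "group", "twice_group"])


class TestDemographicStats:
    def test_chisq_published_gender_table(self):
        assert mc.chisq_from_counts([[18, 68], [23, 50]]) == pytest.approx(
            2.308, abs=1e-3)

    def test_chisq_equal_proportions_zero(self):
        assert mc.chisq_from_counts([[10, 10], [10, 10]]) == 0.0

    def test_chisq_matches_hand_oracle(self, rng):
        for _ in range(50):
            table = rng.integers(1, 60, size=(2, 2)).astype(float)
            expected = 0.0
            row, col, tot = table.sum(1), table.sum(0), table.sum()
            for i in range(2):
                for j in range(2):
                    e = row[i] * col[j] / tot
                    expected += (table[i, j] - e) ** 2 / e
            assert mc.chisq_from_counts(table) == pytest.approx(expected, abs=1e-10)
            chi2_ref = stats.chi2_contingency(table, correction=False).statistic
            assert mc.chisq_from_counts(table) == pytest.approx(chi2_ref, abs=1e-10)

    def test_chisq_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            mc.chisq_from_counts([[0, 0], [10, 10]])

    def test_pooled_t_published_tiv_row(self):
        t = mc.pooled_t_from_summary(1422.35, 119.29, 86, 1439.10, 135.95, 73)
        assert t == pytest.approx(-0.827, abs=1e-3)

    def test_pooled_t_identical_summaries_zero(self):
        assert mc.pooled_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10) == 0.0

    def test_pooled_t_closed_form(self):
        # pooled SD = 1, SE = sqrt(2/10) -> t = 1/sqrt(0.2) = 2.236
        assert mc.pooled_t_from_summary(1, 1, 10, 0, 1, 10) == pytest.approx(
            2.2360679, abs=1e-6)

    def test_pooled_t_degenerate_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mc.pooled_t_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)


class TestQcAndStages:
    def _controls(self, n, flagged):
        out = []
        for j in range(n):
            out.append(mc.SubjectRecord(
                subject_id=f"C{j:03d}", group="control", age=22.0,
                sex="female", tiv=1430.0, bmi=21.0, qc_excluded=j < flagged,
            ))
        return out

    def test_qc_exclude_76_minus_3(self):
        kept = mc.qc_exclude(self._controls(76, 3))
        assert len(kept) == 73

    def test_qc_exclude_identity_and_empty(self):
        recs = self._controls(5, 0)
        assert mc.qc_exclude(recs) == recs
        assert mc.qc_exclude(self._controls(5, 5)) == []

    @staticmethod
    def _patient(i, duration):
        return mc.SubjectRecord(
            subject_id=f"P{i:03d}", group="patient", age=22.0, sex="female",
            tiv=1430.0, bmi=21.0, duration_months=float(duration),
        )

    def test_stage_split_boundary_is_long(self):
        recs = [self._patient(i, d) for i, d in enumerate([6, 59, 60, 100])]
        split = mc.stage_split(recs)
        assert split.short_ids == ["P000", "P001"]
        assert split.long_ids == ["P002", "P003"]

    def test_stage_split_allows_empty_long(self):
        recs = [self._patient(i, 6) for i in range(4)]
        split = mc.stage_split(recs)
        assert split.n_long == 0 and split.n_short == 4

    def test_stage_split_partition(self, small_cohort):
        records, _ = small_cohort
        split = mc.stage_split(records)
        assert split.n_short + split.n_long == 86
        assert not set(split.short_ids) & set(split.long_ids)

    def test_stage_split_rejects_subminimum_duration(self):
        with pytest.raises(ValueError, match="inclusion"):
            mc.stage_split([self._patient(0, 3)])


class TestRoiMean:
    def test_single_voxel_region_is_that_column(self, rng):
        ds = tiny_dataset(rng, n_subjects=8, n_mask=5)
        region = np.zeros(ds.mask.shape, dtype=bool)
        idx = tuple(np.argwhere(ds.mask)[2])
        region[idx] = True
        np.testing.assert_array_equal(mc.extract_roi_mean(ds, region), ds.data[:, 2])

    def test_constant_map(self, rng):
        ds = tiny_dataset(rng, n_subjects=8, n_mask=5)
        ds.data[:] = 4.2
        np.testing.assert_allclose(mc.extract_roi_mean(ds, ds.mask), 4.2)

    def test_matches_manual_mean(self, rng):
        ds = tiny_dataset(rng, n_subjects=8, n_mask=5)
        region = np.zeros(ds.mask.shape, dtype=bool)
        for idx in np.argwhere(ds.mask)[[0, 3, 4]]:
            region[tuple(idx)] = True
        np.testing.assert_allclose(
            mc.extract_roi_mean(ds, region), ds.data[:, [0, 3, 4]].mean(axis=1),
            atol=1e-14)

    def test_empty_region_rejected(self, rng):
        ds = tiny_dataset(rng, n_subjects=8, n_mask=5)
        with pytest.raises(ValueError, match="empty"):
            mc.extract_roi_mean(ds, np.zeros(ds.mask.shape, dtype=bool))


class TestRoiAncova:
    def test_bonferroni_is_three_times_raw(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        covs = rng.normal(size=(30, 2))
        res = mc.roi_ancova(values, groups, covs)
        for _, row in res.pairwise.iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, 3 * row["p_raw"]), abs=1e-12)

    def test_matches_pingouin_ancova(self, rng):
        import pandas as pd
        import pingouin as pg

        values = rng.normal(size=36)
        groups = np.repeat(["a", "b", "c"], 12)
        covs = rng.normal(size=(36, 2))
        res = mc.roi_ancova(values, groups, covs)
        df = pd.DataFrame({"y": values, "g": groups,
                           "c1": covs[:, 0], "c2": covs[:, 1]})
        ref = pg.ancova(data=df, dv="y", between="g", covar=["c1", "c2"])
        f_ref = float(ref.loc[ref["Source"] == "g", "F"].iloc[0])
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-8)

    def test_planted_shift_detected_in_two_contrasts(self, rng):
        values = np.concatenate([
            rng.normal(0, 1, 25), rng.normal(0, 1, 25), rng.normal(5, 1, 25)])
        groups = np.repeat(["hc", "short", "long"], 25)
        res = mc.roi_ancova(values, groups, rng.normal(size=(75, 1)))
        pw = res.pairwise.set_index("contrast")
        sig = pw["p_bonferroni"] < 0.05
        involving_long = [c for c in pw.index if "long" in c]
        not_long = [c for c in pw.index if "long" not in c]
        assert all(sig[c] for c in involving_long)
        assert not any(sig[c] for c in not_long)

    def test_null_calibration(self):
        """Identical groups (plus covariate effects): the F test rejects at
        roughly its nominal 5% level."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            covs = rng.normal(size=(45, 1))
            values = 0.8 * covs[:, 0] + rng.normal(size=45)
            groups = np.repeat(["a", "b", "c"], 15)
            res = mc.roi_ancova(values, groups, covs)
            rejections += res.p_value < 0.05
        # binomial 99% band around 0.05 for n=300
        assert 4 <= rejections <= 27

    def test_small_level_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            mc.roi_ancova(rng.normal(size=5),
                          ["a", "a", "b", "b", "c"], None)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 40))
        r, p = mc.partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_relation_gives_r_one(self, rng):
        covs = rng.normal(size=(40, 2))
        x = rng.normal(size=40)
        y = x + covs @ np.array([2.0, -1.0])
        r, _ = mc.partial_correlation(x, y, covs)
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_matches_residual_oracle_and_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        for _ in range(20):
            covs = rng.normal(size=(30, 2))
            x, y = rng.normal(size=(2, 30))
            r, p = mc.partial_correlation(x, y, covs)
            # independent residual oracle via lstsq
            Z = np.column_stack([np.ones(30), covs])
            rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
            ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)
            df = pd.DataFrame({"x": x, "y": y, "c1": covs[:, 0], "c2": covs[:, 1]})
            ref = pg.partial_corr(data=df, x="x", y="y", covar=["c1", "c2"])
            assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
            assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_constant_residuals_rejected(self, rng):
        covs = rng.normal(size=(20, 1))
        x = 3.0 * covs[:, 0] + 1.0  # fully explained by the covariate
        with pytest.raises(ValueError, match="constant"):
            mc.partial_correlation(x, rng.normal(size=20), covs)
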