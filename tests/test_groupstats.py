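"""Group statistics: demographics tests, voxelwise GLM, smoothness,
RFT and permutation cluster inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcfmri.groupstats import (DesignMatrix, compare_demographics,
                               fit_voxelwise_glm, estimate_smoothness,
                               grf_cluster_correct, permutation_cluster_correct,
                               cluster_table, StatMap)
from dcfmri.validation import simulate_subject_maps, smoothness_recovery


def make_pheno(m_pat, f_pat, m_ctl, f_ctl, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, (group, sex) in enumerate(
            [("patient", "M")] * m_pat + [("patient", "F")] * f_pat
            + [("control", "M")] * m_ctl + [("control", "F")] * f_ctl):
        rows.append({"id": f"s{i}", "group": group, "sex": sex,
                     "age": float(rng.normal(28, 7)),
                     "education": float(rng.normal(12, 3)),
                     "hrsd17": float(rng.integers(17, 30)) if group == "patient" else None})
    return pd.DataFrame(rows)


def two_group_design(n_per_group):
    group = np.r_[np.ones(n_per_group), np.zeros(n_per_group)]
    X = np.column_stack([np.ones(2 * n_per_group), group])
    return DesignMatrix(X=X, columns=["intercept", "group"],
                        contrast=np.array([0.0, 1.0]),
                        subject_ids=[f"s{i}" for i in range(2 * n_per_group)])


class TestDemographics:
    def test_chisquare_gender_table_reproduces_reported_p(self):
        """102/96 male/female patients vs 130/104 controls -> p = 0.401."""
        pheno = make_pheno(102, 96, 130, 104)
        rep = compare_demographics(pheno).set_index("variable")
        assert rep.loc["sex", "p_value"] == pytest.approx(0.401, abs=5e-4)

    def test_identical_groups_give_null_statistics(self):
        pheno = make_pheno(10, 10, 10, 10)
        # clone ages/education across groups for an exact null
        vals_age = np.tile(np.arange(20.0, 40.0), 2)
        pheno["age"] = vals_age
        pheno["education"] = np.tile(np.arange(8.0, 28.0), 2)
        rep = compare_demographics(pheno).set_index("variable")
        assert rep.loc["sex", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert rep.loc["sex", "p_value"] == pytest.approx(1.0)
        assert rep.loc["age", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert rep.loc["age", "p_value"] == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        pheno = make_pheno(10, 0, 12, 0)  # no women at all
        with pytest.raises(ValueError, match="margin"):
            compare_demographics(pheno)


class TestVoxelwiseGLM:
    def test_matches_pooled_two_sample_t(self):
        """Intercept+group model reproduces the textbook pooled t exactly."""
        maps = [np.full((2, 2, 1), v) for v in [0.0, 0.0, 1.0, 1.0,
                                                2.0, 2.0, 3.0, 3.0]]
        design = two_group_design(4)
        mask = np.ones((2, 2, 1), bool)
        stat, resid = fit_voxelwise_glm(maps, design, mask, np.eye(4))
        expected = stats.ttest_ind([0, 0, 1, 1], [2, 2, 3, 3], equal_var=True)
        assert stat.df == 6
        np.testing.assert_allclose(stat.t[mask], expected.statistic, atol=1e-10)

    def test_pooled_t_at_every_voxel_random_maps(self, rng):
        n = 8
        maps = list(rng.standard_normal((2 * n, 4, 4, 3)))
        design = two_group_design(n)
        mask = np.ones((4, 4, 3), bool)
        stat, _ = fit_voxelwise_glm(maps, design, mask, np.eye(4))
        a = np.array(maps[:n])
        b = np.array(maps[n:])
        ref = stats.ttest_ind(a.reshape(n, -1), b.reshape(n, -1),
                              equal_var=True).statistic.reshape(4, 4, 3)
        np.testing.assert_allclose(stat.t, ref, atol=1e-10)

    def test_orthogonal_covariate_changes_only_df(self, rng):
        n = 6
        maps = list(rng.standard_normal((2 * n, 3, 3, 2)))
        mask = np.ones((3, 3, 2), bool)
        d1 = two_group_design(n)
        # covariate orthogonal to the existing columns and to the data
        cov = np.r_[np.ones(n // 2), -np.ones(n // 2)] / np.sqrt(n)
        cov = np.r_[cov, cov]
        cov = cov - d1.X @ np.linalg.lstsq(d1.X, cov, rcond=None)[0]
        X2 = np.column_stack([d1.X, cov])
        d2 = DesignMatrix(X=X2, columns=d1.columns + ["extra"],
                          contrast=np.r_[d1.contrast, 0.0],
                          subject_ids=d1.subject_ids)
        s1, r1 = fit_voxelwise_glm(maps, d1, mask, np.eye(4))
        s2, r2 = fit_voxelwise_glm(maps, d2, mask, np.eye(4))
        assert s2.df == s1.df - 1
        # effect and contrast variance unchanged by an orthogonal column;
        # t changes only through sigma-hat's df
        rss1 = (r1 ** 2).sum(0)
        rss2 = (r2 ** 2).sum(0)
        ratio = (s1.t[mask] / s2.t[mask])
        np.testing.assert_allclose(
            ratio, np.sqrt((rss2 / s2.df) / (rss1 / s1.df)), atol=1e-8)

    def test_null_pvalues_uniform_under_permutation(self, rng):
        """Exchangeable null maps -> approximately uniform voxel p-values."""
        n = 20
        maps = list(simulate_subject_maps(rng, 2 * n, (16, 16, 10), 1.0))
        design = two_group_design(n)
        mask = np.ones((16, 16, 10), bool)
        stat, _ = fit_voxelwise_glm(maps, design, mask, np.eye(4))
        # subsample a sparse lattice to decorrelate neighbouring voxels
        p = 2 * stats.t.sf(np.abs(stat.t[::3, ::3, ::3].ravel()), stat.df)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.r_[np.ones(4), np.zeros(4)],
                             np.r_[np.ones(4), np.zeros(4)]])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X=X, columns=["intercept", "group", "dup"],
                         contrast=np.array([0, 1.0, 0]),
                         subject_ids=[str(i) for i in range(8)])


class TestSmoothness:
    def test_recovers_known_kernel_within_15pct(self):
        res = smoothness_recovery(seed=11)
        assert res["max_rel_error"] < 0.15

    def test_unsmoothed_noise_estimates_below_smoothed(self, rng):
        dims = (20, 20, 20)
        mask = np.ones(dims, bool)
        vs = np.array([3.0, 3.0, 3.0])
        raw = rng.standard_normal((6,) + dims)
        from scipy.ndimage import gaussian_filter
        smooth = np.array([gaussian_filter(f, 1.2) for f in raw])
        f_raw, _ = estimate_smoothness(raw, mask, vs)
        f_sm, _ = estimate_smoothness(smooth, mask, vs)
        assert np.all(f_raw < f_sm)

    def test_resel_count_scales_with_volume(self, rng):
        vs = np.array([3.0, 3.0, 3.0])
        from scipy.ndimage import gaussian_filter
        f1 = np.array([gaussian_filter(rng.standard_normal((16, 16, 16)), 1.0)
                       for _ in range(8)])
        f2 = np.array([gaussian_filter(rng.standard_normal((32, 16, 16)), 1.0)
                       for _ in range(8)])
        _, r1 = estimate_smoothness(f1, np.ones((16, 16, 16), bool), vs)
        _, r2 = estimate_smoothness(f2, np.ones((32, 16, 16), bool), vs)
        assert r2 / r1 == pytest.approx(2.0, rel=0.15)


class TestClusterInference:
    def _null_stat(self, resels=300.0, df=38, dims=(20, 20, 12)):
        return StatMap(t=np.zeros(dims), df=df, mask=np.ones(dims, bool),
                       affine=np.eye(4), residual_fwhm_mm=np.array([6.0] * 3),
                       resel_count=resels)

    def test_all_zero_t_map_gives_no_clusters(self):
        assert grf_cluster_correct(self._null_stat()) == []

    def test_planted_blob_survives_and_sign_tracks(self, rng):
        stat = self._null_stat()
        stat.t[5:10, 5:10, 4:8] = 8.0
        pos = grf_cluster_correct(stat)
        assert len(pos) == 1 and pos[0].sign == "positive"
        assert pos[0].n_voxels == 5 * 5 * 4
        stat.t *= -1
        neg = grf_cluster_correct(stat)
        assert len(neg) == 1 and neg[0].sign == "negative"
        assert neg[0].n_voxels == pos[0].n_voxels
        assert neg[0].p_corrected == pytest.approx(pos[0].p_corrected)

    def test_corrected_p_monotone_in_extent(self):
        stat = self._null_stat()
        stat.t[2:4, 2:4, 2:4] = 8.0      # 8 voxels
        stat.t[10:14, 10:14, 4:8] = 8.0  # 64 voxels
        recs = grf_cluster_correct(stat, cluster_p=1.0 + 1e-9)
        by_size = sorted(recs, key=lambda c: c.n_voxels)
        assert by_size[0].p_corrected > by_size[-1].p_corrected

    def test_df_guard(self):
        stat = self._null_stat(df=5)
        with pytest.raises(ValueError, match="df"):
            grf_cluster_correct(stat)

    def test_peak_inside_cluster_and_world_coordinates(self):
        stat = self._null_stat()
        stat.t[5:8, 5:8, 5:8] = 6.0
        stat.t[6, 6, 6] = 9.0
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        aff[:3, 3] = [-30.0, -30.0, -18.0]
        stat.affine = aff
        rec = grf_cluster_correct(stat)[0]
        assert rec.peak_t == 9.0
        assert rec.peak_coord_world == (-12.0, -12.0, 0.0)
        assert rec.mask[6, 6, 6]

    def test_permutation_p_floor_and_determinism(self, rng):
        n = 10
        dims = (12, 12, 8)
        mask = np.ones(dims, bool)
        maps = simulate_subject_maps(rng, 2 * n, dims, 1.5)
        blob = np.zeros(dims, bool)
        blob[4:8, 4:8, 3:6] = True
        for i in range(n):
            maps[i][blob] += 3.0
        design = two_group_design(n)
        a = permutation_cluster_correct(list(maps), design, mask, np.eye(4),
                                        n_perm=199, seed=5)
        b = permutation_cluster_correct(list(maps), design, mask, np.eye(4),
                                        n_perm=199, seed=5)
        assert len(a) >= 1
        assert a[0].p_corrected >= 1.0 / 200.0  # permutation p floor
        assert [(c.n_voxels, c.p_corrected) for c in a] == \
               [(c.n_voxels, c.p_corrected) for c in b]

    def test_low_nperm_warns_but_runs(self, rng, caplog):
        n = 6
        dims = (8, 8, 6)
        maps = list(simulate_subject_maps(rng, 2 * n, dims, 1.0))
        design = two_group_design(n)
        import logging
        with caplog.at_level(logging.WARNING, logger="dcfmri.groupstats"):
            permutation_cluster_correct(maps, design, np.ones(dims, bool),
                                        np.eye(4), n_perm=50, seed=1)
        assert any("n_perm" in r.message for r in caplog.records)

    def test_sign_flip_swaps_cluster_sets(self, rng):
        n = 10
        dims = (14, 14, 10)
        mask = np.ones(dims, bool)
        maps = simulate_subject_maps(rng, 2 * n, dims, 1.5)
        blob = np.zeros(dims, bool)
        blob[4:9, 4:9, 3:7] = True
        for i in range(n):
            maps[i][blob] += 2.5
        design = two_group_design(n)
        s1, r1 = fit_voxelwise_glm(list(maps), design, mask, np.eye(4))
        s2, r2 = fit_voxelwise_glm([-m for m in maps], design, mask, np.eye(4))
        vs = np.array([3.0] * 3)
        f1, rc1 = estimate_smoothness(r1, mask, vs)
        s1.residual_fwhm_mm, s1.resel_count = f1, rc1
        s2.residual_fwhm_mm, s2.resel_count = f1, rc1
        c1 = grf_cluster_correct(s1)
        c2 = grf_cluster_correct(s2)
        assert {(c.n_voxels, c.sign) for c in c1} == \
               {(c.n_voxels, {"positive": "negative",
                              "negative": "positive"}[c.sign]) for c in c2}


class TestClusterTable:
    def test_empty_list_gives_header_only(self):
        tab = cluster_table([])
        assert len(tab) == 0
        assert "peak_x_mm" in tab.columns

    def test_single_voxel_cluster_identity_affine(self):
        stat = StatMap(t=np.zeros((6, 6, 6)), df=40,
                       mask=np.ones((6, 6, 6), bool), affine=np.eye(4),
                       residual_fwhm_mm=np.array([2.0] * 3), resel_count=27.0)
        stat.t[0, 0, 0] = 50.0
        recs = grf_cluster_correct(stat, cluster_p=1.0 + 1e-9)
        tab = cluster_table(recs)
        row = tab.iloc[0]
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (0.0, 0.0, 0.0)
        assert row.n_voxels == 1
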