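"""Group-level inference: t maps, GLM, partial correlation, demographics."""

import numpy as np
import pandas as pd
import pytest

from hubcausal.clusters import McResult
from hubcausal.grids import BinaryMask, ScalarMap, VolumeGrid
from hubcausal.group import (
    GroupContrastGLM,
    build_design,
    chi_square_2x2,
    cluster_mean_values,
    combine_group_masks,
    correlation_report,
    demographics_table,
    one_sample_map,
    partial_pearson,
    two_sample_glm_map,
    two_sample_t_from_summary,
)


@pytest.fixture
def grid4():
    return VolumeGrid.from_spacing((4, 4, 4), origin_mm=(0, 0, 0))


@pytest.fixture
def mask4(grid4):
    return BinaryMask(grid4, np.ones(grid4.dims, dtype=bool))


def subjects_frame(n_pat=6, n_ctl=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n, prefix in (("tinnitus", n_pat, "t"), ("control", n_ctl, "c")):
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{prefix}{i}",
                    "group": g,
                    "age": float(rng.integers(30, 70)),
                    "sex": rng.choice(["male", "female"]),
                    "education": float(rng.integers(8, 20)),
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


def random_maps(grid, n, rng, offset=0.0):
    return [
        ScalarMap(grid, rng.standard_normal(grid.dims) + offset, kind="degree_z")
        for _ in range(n)
    ]


class TestOneSample:
    def test_hand_computed_t(self, grid4, mask4):
        # values {1,2,3}: t = mean/(sd/sqrt(n)) = 2/(1/sqrt(3)) = 3.4641
        maps = [ScalarMap(grid4, np.full(grid4.dims, v)) for v in (1.0, 2.0, 3.0)]
        t = one_sample_map(maps, mask4)
        np.testing.assert_allclose(t.data, 2 * np.sqrt(3), atol=1e-10)

    def test_sign_flip_antisymmetry(self, grid4, mask4, rng):
        maps = random_maps(grid4, 5, rng)
        flipped = [ScalarMap(grid4, -m.data) for m in maps]
        t = one_sample_map(maps, mask4)
        t_neg = one_sample_map(flipped, mask4)
        np.testing.assert_allclose(t_neg.data, -t.data, atol=1e-10)

    def test_identical_maps_flagged_degenerate(self, grid4, mask4):
        maps = [ScalarMap(grid4, np.ones(grid4.dims))] * 3
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t = one_sample_map(maps, mask4)
        assert np.all(t.data == 0)


class TestTwoSampleGLM:
    def test_constant_covariates_reduce_to_pooled_t(self, grid4, mask4, rng):
        from scipy.stats import ttest_ind

        df = subjects_frame(5, 7)
        df["age"] = 50.0
        df["sex"] = "male"
        df["education"] = 12.0
        maps = random_maps(grid4, 12, rng)
        design = build_design(df)
        assert design.columns == ["intercept", "group"]
        t = two_sample_glm_map(maps, design, mask4)
        stack = np.stack([m.data for m in maps])
        expected = ttest_ind(stack[:5], stack[5:], axis=0, equal_var=True).statistic
        np.testing.assert_allclose(t.data, expected, atol=1e-8)

    def test_matches_pseudoinverse_oracle(self, grid4, mask4, rng):
        df = subjects_frame(3, 3)
        maps = random_maps(grid4, 6, rng)
        design = build_design(df)
        t = two_sample_glm_map(maps, design, mask4)
        # independent normal-equations route, voxel by voxel
        X = design.matrix
        g = design.group_column
        V = np.stack([m.data.ravel() for m in maps])
        for v in [0, 17, 63]:
            beta = np.linalg.pinv(X) @ V[:, v]
            resid = V[:, v] - X @ beta
            s2 = resid @ resid / (X.shape[0] - X.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[g, g])
            np.testing.assert_allclose(t.data.ravel()[v], beta[g] / se, atol=1e-10)

    def test_matches_statsmodels_ols(self, grid4, mask4, rng):
        import statsmodels.api as sm

        df = subjects_frame(6, 6, seed=3)
        maps = random_maps(grid4, 12, rng)
        design = build_design(df)
        t = two_sample_glm_map(maps, design, mask4)
        v = (2, 1, 3)
        y = np.array([m.data[v] for m in maps])
        fit = sm.OLS(y, design.matrix).fit()
        np.testing.assert_allclose(t.data[v], fit.tvalues[design.group_column], atol=1e-8)

    def test_subject_permutation_invariance(self, grid4, mask4, rng):
        df = subjects_frame(5, 5, seed=1)
        maps = random_maps(grid4, 10, rng)
        design = build_design(df)
        t1 = two_sample_glm_map(maps, design, mask4)
        perm = rng.permutation(10)
        df2 = df.iloc[perm].reset_index(drop=True)
        maps2 = [maps[i] for i in perm]
        t2 = two_sample_glm_map(maps2, build_design(df2), mask4)
        np.testing.assert_allclose(t2.data, t1.data, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        df = subjects_frame(4, 4)
        df["education"] = df["age"]  # perfectly collinear
        with pytest.raises(ValueError, match="rank"):
            build_design(df)

    def test_excluded_subjects_dropped(self):
        df = subjects_frame(5, 5)
        df.loc[0, "excluded"] = True
        design = build_design(df)
        assert len(design.subject_ids) == 9
        assert "t0" not in design.subject_ids


class TestCombineMasks:
    def _mc(self, min_size=2):
        return McResult(min_size, np.zeros(100, int), 0.01, 0.01, 100, 6.0, 5.0)

    def test_identical_groups_union_equals_either(self, grid4, mask4):
        data = np.zeros(grid4.dims)
        data[1:3, 1:3, 1:3] = 5.0
        tmaps = [ScalarMap(grid4, data, kind="tstat")] * 2
        union = combine_group_masks(tmaps, mask4, self._mc(), [2.0, 2.0])
        assert union.n_true == 8

    def test_disjoint_regions_sizes_add(self, grid4, mask4):
        a = np.zeros(grid4.dims)
        a[0:2, 0:2, 0] = 5.0
        b = np.zeros(grid4.dims)
        b[2:4, 2:4, 3] = 5.0
        union = combine_group_masks(
            [ScalarMap(grid4, a, kind="tstat"), ScalarMap(grid4, b, kind="tstat")],
            mask4, self._mc(), [2.0, 2.0],
        )
        assert union.n_true == 8

    def test_empty_union_falls_back_to_gm_mask(self, grid4, mask4):
        zero = ScalarMap(grid4, np.zeros(grid4.dims), kind="tstat")
        with pytest.warns(RuntimeWarning, match="falling back"):
            union = combine_group_masks([zero, zero], mask4, self._mc(), [2.0, 2.0])
        assert union.n_true == mask4.n_true


class TestClusterMeans:
    def test_single_voxel_cluster(self, grid4, mask4, rng):
        maps = random_maps(grid4, 4, rng)
        cmask = np.zeros(grid4.dims, dtype=bool)
        cmask[2, 2, 2] = True
        vals = cluster_mean_values(maps, BinaryMask(grid4, cmask))
        np.testing.assert_allclose(vals, [m.data[2, 2, 2] for m in maps])

    def test_constant_map_gives_constant(self, grid4, rng):
        maps = [ScalarMap(grid4, np.full(grid4.dims, 3.5))] * 3
        cmask = np.zeros(grid4.dims, dtype=bool)
        cmask[0, :2, 0] = True
        vals = cluster_mean_values(maps, BinaryMask(grid4, cmask))
        np.testing.assert_allclose(vals, 3.5)

    def test_three_voxel_cluster_hand_mean(self, grid4):
        data = np.zeros(grid4.dims)
        data[0, 0, 0], data[1, 0, 0], data[2, 0, 0] = 1.0, 2.0, 6.0
        cmask = np.zeros(grid4.dims, dtype=bool)
        cmask[:3, 0, 0] = True
        vals = cluster_mean_values([ScalarMap(grid4, data)], BinaryMask(grid4, cmask))
        np.testing.assert_allclose(vals, [3.0])

    def test_empty_cluster_rejected(self, grid4, rng):
        with pytest.raises(ValueError, match="empty"):
            cluster_mean_values(
                random_maps(grid4, 3, rng),
                BinaryMask(grid4, np.zeros(grid4.dims, dtype=bool)),
            )


class TestPartialPearson:
    def test_orthogonal_covariates_reduce_to_plain_pearson(self, rng):
        n = 40
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        # covariate orthogonal to both by construction (Gram-Schmidt)
        c = rng.standard_normal(n)
        A = np.column_stack([np.ones(n), x, y])
        c = c - A @ np.linalg.lstsq(A, c, rcond=None)[0]
        r_partial, _ = partial_pearson(x, y, c[:, None])
        r_plain = np.corrcoef(x, y)[0, 1]
        np.testing.assert_allclose(r_partial, r_plain, atol=1e-10)

    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(30)
        r, p = partial_pearson(x, x.copy(), None)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_matches_two_stage_regression_oracle(self, rng):
        n = 10
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        covs = rng.standard_normal((n, 3))
        r, p = partial_pearson(x, y, covs)
        X = np.column_stack([np.ones(n), covs])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(r, np.corrcoef(rx, ry)[0, 1], atol=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        n = 24
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        covs = rng.standard_normal((n, 3))
        r, p = partial_pearson(x, y, covs)
        df = pd.DataFrame(
            {"x": x, "y": y, "c1": covs[:, 0], "c2": covs[:, 1], "c3": covs[:, 2]}
        )
        res = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
        np.testing.assert_allclose(r, res["r"].iloc[0], atol=1e-8)
        np.testing.assert_allclose(p, res["p_val"].iloc[0], atol=1e-8)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            partial_pearson(np.ones(4), np.ones(4), rng.standard_normal((4, 3)))


class TestDemographics:
    def test_cohort_summary_t_test(self):
        # printed group summaries reproduce the published p within rounding
        t, p = two_sample_t_from_summary(50.8, 12.4, 24, 44.7, 15.4, 22)
        assert t == pytest.approx(1.4854, abs=1e-3)
        assert p == pytest.approx(0.1446, abs=5e-4)

    def test_sex_chi_square_without_correction(self):
        chi2, p = chi_square_2x2([[9, 15], [9, 13]])
        assert chi2 == pytest.approx(0.056, abs=5e-3)
        assert p == pytest.approx(0.813, abs=1e-3)

    def test_identical_group_summaries_give_p_one(self):
        _, p = two_sample_t_from_summary(50.0, 10.0, 20, 50.0, 10.0, 20)
        assert p == pytest.approx(1.0)

    def test_table_from_records(self):
        df = subjects_frame(8, 8, seed=5)
        df["thq"] = np.where(df["group"] == "tinnitus", 50.0, np.nan)
        df["tinnitus_duration"] = np.where(df["group"] == "tinnitus", 40.0, np.nan)
        df["hearing_left"] = 13.0
        df["hearing_right"] = 14.0
        table = demographics_table(df)
        assert set(table["variable"]) >= {"age", "education", "sex (male:female)"}
        thq_row = table[table["variable"] == "thq"].iloc[0]
        assert thq_row["control"] == "-" and thq_row["p"] == "-"


class TestCorrelationReport:
    def test_bonferroni_never_below_raw_and_capped(self, rng):
        n = 24
        clusters = {f"c{i}": rng.standard_normal(n) for i in range(3)}
        clinical = {"THQ": rng.standard_normal(n), "duration": rng.standard_normal(n)}
        covs = rng.standard_normal((n, 3))
        report = correlation_report(clusters, clinical, covs)
        assert (report["n_tests"] == 6).all()
        assert (report["p_bonferroni"] >= report["p_raw"] - 1e-15).all()
        assert (report["p_bonferroni"] <= 1.0).all()
        assert (report["r"].abs() <= 1.0).all()


def test_group_glm_model_interface(grid4, mask4, rng):
    df = subjects_frame(6, 6, seed=2)
    maps = random_maps(grid4, 12, rng)
    res = GroupContrastGLM.from_dataframe(maps, df, mask4).fit()
    assert res.dof == 12 - res.design.matrix.shape[1]
    text = res.summary()
    assert "6 tinnitus vs 6 control" in text
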