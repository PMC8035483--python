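import numpy as np
import pytest
from scipy import stats as st

from connsweep.stats import (
    StatsError,
    ancova_group_test,
    bh_fdr,
    chi_square_test,
    classify_cognitive_status,
    one_way_anova_from_summary,
    partial_correlation_test,
    two_sample_t_from_summary,
)


class TestClassification:
    @pytest.mark.parametrize("moca,expected", [(25, "CI"), (26, "NCI"), (30, "NCI"), (0, "CI")])
    def test_moca_threshold(self, moca, expected):
        assert classify_cognitive_status(moca) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            classify_cognitive_status(31)


class TestChiSquare:
    def test_published_sex_table(self):
        res = chi_square_test(np.array([[23, 13], [20, 10], [30, 18]]))
        assert res.p == pytest.approx(0.933, abs=0.005)
        assert res.df == (2.0,)

    def test_identical_proportions_give_unity(self):
        res = chi_square_test(np.array([[10, 20], [20, 40]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        res = chi_square_test(np.array([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.df == (1.0,)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_square_test(np.array([[0, 0], [5, 3]]))


class TestTTestFromSummary:
    def test_published_creatinine_row_pooled(self):
        res = two_sample_t_from_summary(36, 764.40, 229.66, 30, 714.62, 182.45, "pooled")
        assert res.p == pytest.approx(0.340, abs=0.005)

    def test_published_hemoglobin_row_welch(self):
        res = two_sample_t_from_summary(36, 83.66, 17.52, 30, 95.22, 22.78, "welch")
        assert res.p == pytest.approx(0.027, abs=0.005)

    def test_equal_means_give_unity(self):
        res = two_sample_t_from_summary(10, 5.0, 1.0, 12, 5.0, 1.2, "pooled")
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_agrees_with_raw_data_test(self, rng):
        a, b = rng.normal(size=(2, 40)) + np.array([[0.0], [0.4]])
        res = two_sample_t_from_summary(
            40, a.mean(), a.std(ddof=1), 40, b.mean(), b.std(ddof=1), "pooled"
        )
        t_raw, p_raw = st.ttest_ind(a, b)
        assert abs(res.p - p_raw) < 1e-10


class TestAnovaFromSummary:
    def test_published_age_row(self):
        res = one_way_anova_from_summary(
            [(36, 31.19, 7.90), (30, 31.33, 7.09), (48, 31.93, 7.99)]
        )
        assert res.p == pytest.approx(0.896, abs=0.005)

    def test_equal_means_give_zero_f(self):
        res = one_way_anova_from_summary([(10, 2.0, 1.0), (15, 2.0, 0.5)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=(2, 25)) + np.array([[0.0], [0.6]])
        t_res = two_sample_t_from_summary(
            25, a.mean(), a.std(ddof=1), 25, b.mean(), b.std(ddof=1), "pooled"
        )
        f_res = one_way_anova_from_summary(
            [(25, a.mean(), a.std(ddof=1)), (25, b.mean(), b.std(ddof=1))]
        )
        assert f_res.statistic == pytest.approx(t_res.statistic**2, abs=1e-10)

    def test_agrees_with_raw_data_anova(self, rng):
        groups = [rng.normal(loc=m, size=n) for n, m in [(12, 0.0), (15, 0.3), (18, -0.2)]]
        res = one_way_anova_from_summary(
            [(len(g), g.mean(), g.std(ddof=1)) for g in groups]
        )
        f_raw, p_raw = st.f_oneway(*groups)
        assert abs(res.p - p_raw) < 1e-10


# fixed 12-row worked dataset for the ANCOVA oracle check
ANCOVA_Y = np.array([3.1, 2.7, 3.5, 2.9, 4.2, 3.8, 4.0, 4.4, 5.1, 4.8, 5.5, 5.0])
ANCOVA_GROUP = np.array(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
ANCOVA_COV = np.array(
    [[21, 0], [24, 1], [30, 0], [27, 1], [22, 1], [28, 0],
     [25, 0], [31, 1], [23, 0], [26, 1], [29, 1], [33, 0]], dtype=float
)


def ancova_oracle(y, group, cov):
    """Explicit normal-equations extra-sum-of-squares F test."""
    levels = sorted(set(group))
    n = len(y)
    dummies = np.column_stack([(group == lev).astype(float) for lev in levels[1:]])
    x_full = np.column_stack([np.ones(n), cov, dummies])
    x_red = np.column_stack([np.ones(n), cov])

    def sse(x):
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        r = y - x @ beta
        return r @ r

    df1 = len(levels) - 1
    df2 = n - x_full.shape[1]
    f = ((sse(x_red) - sse(x_full)) / df1) / (sse(x_full) / df2)
    return f, float(st.f.sf(f, df1, df2))


class TestAncova:
    def test_matches_normal_equations_oracle(self):
        res = ancova_group_test(ANCOVA_Y, ANCOVA_GROUP, ANCOVA_COV)
        f_ref, p_ref = ancova_oracle(ANCOVA_Y, ANCOVA_GROUP, ANCOVA_COV)
        assert res.statistic == pytest.approx(f_ref, abs=1e-8)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_reduces_to_anova_without_covariates(self, rng):
        y = rng.normal(size=30)
        group = np.repeat(["A", "B", "C"], 10)
        res = ancova_group_test(y, group, None)
        f_raw, p_raw = st.f_oneway(y[:10], y[10:20], y[20:])
        assert res.statistic == pytest.approx(f_raw, abs=1e-10)
        assert res.p == pytest.approx(p_raw, abs=1e-10)

    def test_orthogonal_covariates_leave_f_unchanged(self, rng):
        group = np.repeat(["A", "B", "C"], 12)
        y = rng.normal(size=36) + np.repeat([0.0, 0.5, 1.0], 12)
        # covariate jointly orthogonal to intercept, group dummies, and y:
        # its coefficient is exactly zero, so the sums of squares are those of
        # the plain ANOVA and F differs only through the error d.o.f.
        basis = np.column_stack([
            np.ones(36), (group == "B").astype(float), (group == "C").astype(float), y
        ])
        cov = rng.normal(size=36)
        cov -= basis @ np.linalg.lstsq(basis, cov, rcond=None)[0]
        with_cov = ancova_group_test(y, group, cov[:, None])
        without = ancova_group_test(y, group, None)
        assert with_cov.statistic == pytest.approx(without.statistic * 32 / 33, abs=1e-8)
        assert without.df == (2.0, 33.0) and with_cov.df == (2.0, 32.0)

    def test_posthoc_bonferroni_and_direction(self, rng):
        y = np.concatenate([rng.normal(size=15), rng.normal(size=15) + 2.0,
                            rng.normal(size=15) + 4.0])
        group = np.repeat(["lo", "mid", "hi"], 15)
        res = ancova_group_test(y, group, None)
        assert res.p < 1e-6
        assert res.effect_direction == "mid > lo > hi" or "hi" in res.effect_direction
        assert all(0 <= p <= 1 for p in res.posthoc.values())
        assert res.posthoc[("hi", "lo")] < 0.001

    def test_type_one_error_calibrated(self):
        # permuted-null simulation: rejection rate at alpha=.05 stays near .05
        rng = np.random.default_rng(2024)
        n = 114
        group = np.array(["CI"] * 36 + ["NCI"] * 30 + ["HC"] * 48)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(size=n)
            cov = np.column_stack([rng.normal(size=n), rng.integers(0, 2, size=n)])
            perm = rng.permutation(n)
            if ancova_group_test(y, group[perm], cov).p < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_collinear_design_rejected(self, rng):
        y = rng.normal(size=20)
        group = np.repeat(["A", "B"], 10)
        cov = (group == "B").astype(float)[:, None]  # aliases the dummy
        with pytest.raises(StatsError, match="rank deficient"):
            ancova_group_test(y, group, cov)


class TestPartialCorrelation:
    def test_no_covariates_reduce_to_pearson(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = partial_correlation_test(x, y, None)
        r_ref, p_ref = st.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-10)

    def test_identical_vectors_give_unit_r(self, rng):
        x = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        res = partial_correlation_test(x, x.copy(), cov)
        assert res.r == pytest.approx(1.0)

    def test_shared_confounder_fully_removed(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.normal(size=n)
        c = rng.normal(size=n)
        y = c.copy()
        res = partial_correlation_test(x, y + 1e-8 * rng.normal(size=n), c[:, None])
        assert abs(res.r) < 0.03

    def test_constant_residual_rejected(self, rng):
        c = rng.normal(size=30)
        with pytest.raises(StatsError):
            partial_correlation_test(2.0 * c, rng.normal(size=30), c[:, None])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_worked_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=25)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_flat_p_fixed_point(self):
        q = bh_fdr(np.full(8, 0.05))
        np.testing.assert_allclose(q, 0.05, atol=1e-12)

    def test_hand_stepup_oracle(self, rng):
        p = rng.uniform(size=12)
        m = len(p)
        order = np.argsort(p)
        q_oracle = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, m * p[i] / rank)
            q_oracle[i] = prev
        np.testing.assert_allclose(bh_fdr(p), q_oracle, atol=1e-12)
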