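"""Group-inference statistics: GLM, corrections, NBS, demographic tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hippnet.inference import (
    DesignMatrix,
    _component_sizes,
    bonferroni_gate,
    chi_squared_2x2,
    edge_index_pairs,
    fdr_bh,
    glm_group_test,
    ks_normality,
    mann_whitney_u,
    nbs,
    partial_correlation_test,
    two_sample_t,
    two_sample_t_pooled,
)


def make_design(n_per_group, rng=None, covariates=True):
    n = 2 * n_per_group
    rng = rng or np.random.default_rng(0)
    phen = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["control"] * n_per_group + ["patient"] * n_per_group,
            "age": rng.uniform(20, 60, n),
            "gender": rng.choice(["male", "female"], n),
        }
    )
    return DesignMatrix.from_phenotypes(phen, covariates=covariates)


class TestGlm:
    def test_constant_response_null(self):
        d = make_design(10)
        res = glm_group_test(np.full(20, 3.3), d)
        assert res.statistic == 0.0 and res.p_two_tailed == 1.0

    def test_saturated_group_effect_coefficient_one(self):
        d = make_design(10, covariates=False)
        res = glm_group_test(d.group.copy(), d)
        assert res.group_coefficient == pytest.approx(1.0, abs=1e-12)

    def test_no_covariates_equals_pooled_t(self, rng):
        d = make_design(15, covariates=False)
        y = rng.standard_normal(30) + 0.4 * d.group
        res = glm_group_test(y, d)
        t, p = two_sample_t(y[d.group == 0], y[d.group == 1])
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_two_tailed == pytest.approx(p, abs=1e-10)

    def test_coefficient_coverage_simulation(self):
        """y = 0.5 group + 0.01 age + noise: 2-se coverage >= 95% nominal-ish."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 500
        d = make_design(100, rng)
        age = d.matrix[:, 2]
        for _ in range(n_rep):
            y = 0.5 * d.group + 0.01 * age + rng.standard_normal(d.n)
            res = glm_group_test(y, d)
            if abs(res.group_coefficient - 0.5) <= 2 * res.standard_error:
                hits += 1
        assert hits / n_rep >= 0.93  # 2 se ~ 95.4% nominal, Monte-Carlo slack

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError):
            DesignMatrix(matrix=np.ones((10, 2)), columns=["intercept", "group"])


class TestCorrections:
    def test_bonferroni_threshold_three_tests(self):
        assert bonferroni_gate([0.0166, 0.0168, 0.5], alpha=0.05, m=3) == [True, False, False]
        assert 0.05 / 3 == pytest.approx(0.0167, abs=5e-5)

    def test_bonferroni_single_test_reduces_to_alpha(self):
        assert bonferroni_gate([0.04], alpha=0.05, m=1) == [True]
        assert bonferroni_gate([0.06], alpha=0.05, m=1) == [False]

    def test_fdr_extremes(self):
        assert fdr_bh([0.0] * 5) == [True] * 5
        assert fdr_bh([1.0] * 5) == [False] * 5

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_fdr_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(24)
        q = 0.05
        # direct-definition oracle: largest i with p_(i) <= i q / m
        order = np.argsort(p)
        m = len(p)
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i * q / m:
                k = i
        expected = np.zeros(m, bool)
        expected[order[:k]] = True
        assert fdr_bh(list(p), q) == list(expected)

    def test_equal_p_vectors_agree_outside_threshold_band(self):
        # with all p equal, BH rejects all iff p <= q while Bonferroni needs
        # p < q/m; decisions coincide whenever p falls outside (q/m, q]
        for p0 in (0.001, 0.9):
            ps = [p0] * 3
            assert fdr_bh(ps, 0.05) == bonferroni_gate(ps, 0.05)


class TestNbs:
    def test_single_supra_edge_single_component(self):
        rows, cols = edge_index_pairs(24)
        supra = np.zeros(len(rows), bool)
        supra[10] = True
        comps = _component_sizes(supra, 24, rows, cols)
        assert len(comps) == 1 and comps[0][1] == 1

    def test_component_edges_are_connected(self):
        rows, cols = edge_index_pairs(24)
        supra = np.zeros(len(rows), bool)
        # edges (0,1), (1,2) connected; edge (5,6) separate
        for e, (i, j) in enumerate(zip(rows, cols)):
            if (i, j) in {(0, 1), (1, 2), (5, 6)}:
                supra[e] = True
        comps = _component_sizes(supra, 24, rows, cols)
        assert sorted(c[1] for c in comps) == [1, 2]

    def _planted_run(self, seed=0, n_per_group=30, n_perm=200):
        rng = np.random.default_rng(seed)
        d = make_design(n_per_group, rng)
        y = rng.standard_normal((d.n, 276))
        planted = [0, 1, 2, 23]  # edges incident to low-index nodes
        y[:, planted] += 1.5 * d.group[:, None]
        return y, d, planted

    def test_planted_effect_detected_in_correct_direction(self):
        y, d, planted = self._planted_run()
        res = nbs(y, d, n_perm=200, rng=1)
        sig = res["patient_gt_control"].significant_components
        assert sig, "planted component not detected"
        found = {e for c in sig for e in c.edge_indices}
        assert set(planted) <= found
        assert not res["control_gt_patient"].significant_components

    def test_corrected_p_monotone_in_component_size(self):
        y, d, _ = self._planted_run()
        # add a second, smaller planted component on disjoint nodes
        rows, cols = edge_index_pairs(24)
        extra = [e for e, (i, j) in enumerate(zip(rows, cols)) if (i, j) == (20, 21)]
        y[:, extra] += 1.5 * d.group[:, None]
        res = nbs(y, d, n_perm=200, rng=2)
        comps = res["patient_gt_control"].components
        sizes = [c.size for c in comps]
        ps = [c.corrected_p for c in comps]
        assert sizes == sorted(sizes, reverse=True)
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            assert p1 <= p2 or s1 == s2

    def test_subject_permutation_leaves_observed_statistics_unchanged(self):
        y, d, _ = self._planted_run(seed=5)
        perm = np.random.default_rng(9).permutation(d.n)
        d2 = DesignMatrix(matrix=d.matrix[perm], columns=d.columns)
        res1 = nbs(y, d, n_perm=150, rng=3)
        res2 = nbs(y[perm], d2, n_perm=150, rng=3)
        s1 = sorted(c.size for c in res1["patient_gt_control"].components)
        s2 = sorted(c.size for c in res2["patient_gt_control"].components)
        assert s1 == s2

    def test_too_few_permutations_rejected(self):
        y, d, _ = self._planted_run()
        with pytest.raises(ValueError):
            nbs(y, d, n_perm=50)


class TestPartialCorrelationTest:
    def test_identical_variables_near_one(self, rng):
        x = rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        r, p = partial_correlation_test(x, x, cov)
        assert r == pytest.approx(1.0, abs=1e-10)
        assert p < 1e-10

    def test_degrees_of_freedom_formula(self, rng):
        n, k = 30, 2
        x, y = rng.standard_normal((2, n))
        cov = rng.standard_normal((n, k))
        r, p = partial_correlation_test(x, y, cov)
        df = n - 2 - k
        assert df == 26
        t = r * np.sqrt(df / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 50
        x, y = rng.standard_normal((2, n))
        cov = rng.standard_normal((n, 2))
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        exp = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        r, p = partial_correlation_test(x, y, cov)
        assert r == pytest.approx(float(exp["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(exp["p_val"].iloc[0]), abs=1e-8)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        n, reps, alpha = 500, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            cov = rng.standard_normal((n, 2))
            x = cov @ [0.5, -0.3] + rng.standard_normal(n)
            y = cov @ [0.2, 0.4] + rng.standard_normal(n)
            _, p = partial_correlation_test(x, y, cov)
            rejections += p < alpha
        assert 0.03 <= rejections / reps <= 0.07


class TestTwoSampleT:
    def test_equal_means_zero(self):
        t, _ = two_sample_t_pooled(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0

    def test_raw_matches_summary_and_scipy(self, rng):
        x = rng.standard_normal(25) + 0.3
        y = rng.standard_normal(30)
        t_raw, p_raw = two_sample_t(x, y)
        t_sum, p_sum = two_sample_t_pooled(x.mean(), x.std(ddof=1), len(x),
                                           y.mean(), y.std(ddof=1), len(y))
        assert t_raw == pytest.approx(t_sum, abs=1e-12)
        sp = stats.ttest_ind(y, x, equal_var=True)
        assert t_raw == pytest.approx(sp.statistic, abs=1e-10)
        assert p_raw == pytest.approx(sp.pvalue, abs=1e-10)


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        U, z, p = mann_whitney_u([1, 2, 3, 4, 5], [10, 11, 12, 13, 14, 15])
        assert U == 0.0
        assert p < 0.05

    def test_identical_multisets_z_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        U, z, p = mann_whitney_u(x, list(x))
        assert z == 0.0 and p == 1.0

    def test_normal_approx_close_to_exact_enumeration(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(9) + 0.5
        U, z, p = mann_whitney_u(x, y)
        exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert U == exact.statistic
        assert p == pytest.approx(exact.pvalue, abs=0.01)

    def test_all_tied_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])


class TestChiSquared:
    def test_proportional_rows_zero(self):
        chi2, p = chi_squared_2x2(20, 10, 40, 20)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_observed_expected_loop(self, rng):
        a, b, c, d = rng.integers(5, 50, 4)
        chi2, _ = chi_squared_2x2(a, b, c, d)
        table = np.array([[a, b], [c, d]], float)
        total = table.sum()
        acc = 0.0
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / total
                acc += (table[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(acc, abs=1e-12)

    def test_matches_scipy_without_continuity(self):
        chi2, p = chi_squared_2x2(57, 14, 51, 23)
        sp = stats.chi2_contingency([[57, 14], [51, 23]], correction=False)
        assert chi2 == pytest.approx(sp.statistic, abs=1e-12)
        assert p == pytest.approx(sp.pvalue, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2(0, 0, 5, 5)


class TestKsNormality:
    def test_large_normal_sample_not_rejected(self):
        rng = np.random.default_rng(4)
        stat, p, is_normal = ks_normality(rng.standard_normal(1000))
        assert is_normal

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(4)
        stat, p, is_normal = ks_normality(rng.exponential(size=200))
        assert not is_normal

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))
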