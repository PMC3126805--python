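"""Two-class tests, median fold changes, BH FDR and one-way ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirprog.diffexpr import (bh_fdr, fc_gene_calls, median_fold_change, oneway_anova,
                              two_class_ttest)
from mirprog.normalization import ExpressionMatrix


def bh_oracle(p):
    """Brute-force step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = [min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)]
    q = np.empty(m)
    q[order] = q_sorted
    return q


def matrix_from(values, scale="log2"):
    values = np.asarray(values, float)
    return ExpressionMatrix([f"g{i}" for i in range(values.shape[0])],
                            [f"s{j}" for j in range(values.shape[1])], values, scale)


class TestTwoClassTtest:
    def test_identical_groups_give_t0_p1(self):
        m = matrix_from([[1.0, 2.0, 1.0, 2.0]])
        res = two_class_ttest(m, np.array([0, 0, 1, 1]))
        assert res["t_statistic"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_strong_separation_p_near_zero(self, rng):
        vals = np.concatenate([rng.normal(0, 1e-3, 3), 1 + rng.normal(0, 1e-3, 3)])
        res = two_class_ttest(matrix_from([vals]), np.array([0, 0, 0, 1, 1, 1]))
        assert res["p_value"].iloc[0] < 1e-6

    def test_zero_variance_flagged(self):
        m = matrix_from([[1.0, 1.0, 1.0, 1.0]])
        res = two_class_ttest(m, np.array([0, 0, 1, 1]))
        assert bool(res["degenerate"].iloc[0])
        assert res["p_value"].iloc[0] == 1.0

    def test_shift_invariance_and_label_swap(self, rng):
        vals = rng.normal(size=(5, 10))
        labels = np.array([0] * 5 + [1] * 5)
        a = two_class_ttest(matrix_from(vals), labels)
        b = two_class_ttest(matrix_from(vals + 7.5), labels)
        c = two_class_ttest(matrix_from(vals), 1 - labels)
        np.testing.assert_allclose(a["t_statistic"], b["t_statistic"], atol=1e-9)
        np.testing.assert_allclose(a["t_statistic"], -c["t_statistic"], atol=1e-9)


class TestMedianFoldChange:
    def test_printed_median_worked_example(self):
        """Group medians 2.3 and 7.9 reproduce the printed 3.43 fold change."""
        g0 = [1.0, 2.3, 4.0]
        g1 = [5.0, 7.9, 11.0]
        m = matrix_from([g0 + g1], scale="linear")
        res = median_fold_change(m, np.array([0, 0, 0, 1, 1, 1]))
        assert res["median_group0"].iloc[0] == pytest.approx(2.3)
        assert res["median_group1"].iloc[0] == pytest.approx(7.9)
        assert res["fold_change"].iloc[0] == pytest.approx(3.43, abs=0.01)

    def test_second_worked_example(self):
        m = matrix_from([[76.8, 76.8, 143.1, 143.1]], scale="linear")
        res = median_fold_change(m, np.array([0, 0, 1, 1]))
        assert res["fold_change"].iloc[0] == pytest.approx(1.863, abs=0.001)

    def test_identical_groups_give_unity(self, rng):
        vals = rng.lognormal(size=6)
        m = matrix_from([np.concatenate([vals, vals])], scale="linear")
        res = median_fold_change(m, np.array([0] * 6 + [1] * 6))
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_reciprocal_under_label_swap(self, rng):
        vals = rng.lognormal(size=(4, 9))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1])
        a = median_fold_change(matrix_from(vals, "linear"), labels)
        b = median_fold_change(matrix_from(vals, "linear"), 1 - labels)
        np.testing.assert_allclose(a["fold_change"] * b["fold_change"], 1.0, rtol=1e-12)

    def test_log2_input_is_inverted_first(self):
        m = matrix_from([[1.0, 1.0, 3.0, 3.0]], scale="log2")  # linear 2 vs 8
        res = median_fold_change(m, np.array([0, 0, 1, 1]))
        assert res["fold_change"].iloc[0] == pytest.approx(4.0)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, ps):
        np.testing.assert_allclose(bh_fdr(ps), bh_oracle(ps), atol=1e-12)


class TestFcGeneCalls:
    def test_no_difference_gives_empty(self):
        m = matrix_from(np.ones((5, 6)), scale="linear")
        calls = fc_gene_calls(m, np.array([0, 0, 0, 1, 1, 1]))
        assert calls == {"up": [], "down": []}

    def test_boundary_is_strict(self):
        m = matrix_from([[1.0, 1.0, 2.0, 2.0],      # exactly FC 2 -> excluded
                         [1.0, 1.0, 2.01, 2.01],    # just above -> up
                         [2.01, 2.01, 1.0, 1.0]],   # just above, other direction -> down
                        scale="linear")
        calls = fc_gene_calls(m, np.array([0, 0, 1, 1]))
        assert calls["up"] == ["g1"]
        assert calls["down"] == ["g2"]

    def test_planted_up_down_sets_recovered(self, rng):
        n_up, n_down, n_null = 40, 35, 60
        n = n_up + n_down + n_null
        labels = np.array([0] * 8 + [1] * 8)
        vals = rng.normal(8, 0.05, size=(n, 16))
        vals[:n_up, labels == 1] += 3.0        # 8-fold up
        vals[n_up:n_up + n_down, labels == 1] -= 3.0
        calls = fc_gene_calls(matrix_from(vals).to_linear(), labels)
        assert calls["up"] == [f"g{i}" for i in range(n_up)]
        assert calls["down"] == [f"g{i}" for i in range(n_up, n_up + n_down)]


class TestOnewayAnova:
    def test_shifted_group_detected(self, rng):
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                            rng.normal(15, 1, 10)])
        g = np.repeat([1, 2, 3], 10)
        f, p = oneway_anova(v, g)
        assert p < 1e-10

    def test_two_groups_equals_t_squared(self, rng):
        vals = rng.normal(size=12)
        labels = np.array([0] * 6 + [1] * 6)
        f, p_f = oneway_anova(vals, labels)
        res = two_class_ttest(matrix_from(vals[None, :]), labels)
        assert f == pytest.approx(float(res["t_statistic"].iloc[0]) ** 2)
        assert p_f == pytest.approx(float(res["p_value"].iloc[0]))

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            v = rng.normal(size=18)
            ps.append(oneway_anova(v, np.repeat([1, 2, 3], 6))[1])
        ps = np.asarray(ps)
        # crude uniformity checks at fixed seed
        assert 0.04 < ps.mean() < 0.96 and (ps < 0.05).mean() < 0.15

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova(np.arange(4.0), np.ones(4))
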