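import itertools

import numpy as np
import pytest
from scipy import stats

import seropanel as sp
from seropanel.io_tables import ContingencyTable


def exact_mw_p(x, y):
    """Full-enumeration two-sided Mann-Whitney p (tie-free data).

    Enumerates the U distribution over all labelings of the pooled sample
    and applies the doubled-smaller-tail convention.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        us.append(np.sum(ranks[list(comb)]) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2 * min(cdf, sf))


class TestMannWhitney:
    def test_identical_samples_symmetric(self):
        res = sp.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_small_exact(self):
        # all 20 labelings of 6 distinct values: the 2 extreme ones give p=0.1
        res = sp.mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.p_value == pytest.approx(0.1)
        assert res.effect_size == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        data = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = data[:n1], data[n1:]
        res = sp.mann_whitney(x, y, mode="exact")
        assert res.p_value == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_normal_approx_close_to_exact_n7(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.permutation(np.arange(1.0, 15.0))
        x, y = data[:7], data[7:]
        p_norm = sp.mann_whitney(x, y, mode="normal").p_value
        assert abs(p_norm - exact_mw_p(x, y)) < 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=9)
        p0 = sp.mann_whitney(x, y).p_value
        p1 = sp.mann_whitney(np.exp(x), np.exp(y)).p_value
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sp.mann_whitney([], [1.0])

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = sp.mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0


class TestKruskalWallis:
    def test_identical_groups_null(self):
        res = sp.kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        # fully tied ranks: H = 0, p = 1 under the tie-corrected statistic
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_h(self):
        res = sp.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(4.571, abs=5e-4)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 2))
        assert res.df == 2

    def test_chi2_close_to_permutation(self):
        groups = [[1.0, 5.0, 2.5], [4.0, 8.0, 2.0], [7.0, 3.0, 6.0]]
        res = sp.kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        h_obs = res.statistic
        count = total = 0
        idx = set(range(9))
        for g1 in itertools.combinations(range(9), 3):
            rest = idx - set(g1)
            for g2 in itertools.combinations(sorted(rest), 3):
                g3 = sorted(rest - set(g2))
                g = [pooled[list(g1)], pooled[list(g2)], pooled[list(g3)]]
                h = stats.kruskal(*g).statistic
                count += h >= h_obs - 1e-12
                total += 1
        assert abs(res.p_value - count / total) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sp.kruskal_wallis([[1.0], []])


class TestCategoricalTests:
    def test_clinical_table_reproductions(self):
        # printed clinical-table contingency rows and their p-values
        subtype = ContingencyTable(
            [[8, 10], [11, 12], [1, 0], [0, 1], [5, 2]],
            ["LumA", "LumB-", "LumB+", "Her2+", "TNBC"],
            ["non_met", "met"],
        )
        assert sp.chi_square_test(subtype).p_value == pytest.approx(0.47, abs=5e-3)
        grade = ContingencyTable([[3, 1], [13, 19], [9, 5]], list("123"), ["n", "m"])
        assert sp.chi_square_test(grade).p_value == pytest.approx(0.20, abs=5e-3)
        multi = ContingencyTable([[4, 2], [21, 23]], ["yes", "no"], ["n", "m"])
        assert sp.chi_square_test(multi, yates="auto").p_value == pytest.approx(
            0.66, abs=5e-3
        )
        her2 = ContingencyTable([[2, 23], [1, 24]], ["pos", "neg"], ["n", "m"])
        assert sp.fisher_exact_2x2(her2).p_value == pytest.approx(1.0, abs=5e-3)

    def test_proportional_table_null(self):
        t = ContingencyTable([[10, 20], [20, 40]], ["a", "b"], ["x", "y"])
        res = sp.chi_square_test(t, yates="off")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        t = ContingencyTable([[0, 0], [3, 4]], ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            sp.chi_square_test(t)

    def test_fisher_diagonal(self):
        t = ContingencyTable([[3, 0], [0, 3]], ["a", "b"], ["x", "y"])
        res = sp.fisher_exact_2x2(t)
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == np.inf

    def test_fisher_degenerate_column(self):
        t = ContingencyTable([[0, 5], [0, 7]], ["a", "b"], ["x", "y"])
        assert sp.fisher_exact_2x2(t).p_value == pytest.approx(1.0)

    def test_fisher_non_2x2_rejected(self):
        t = ContingencyTable([[1, 2], [3, 4], [5, 6]], list("abc"), ["x", "y"])
        with pytest.raises(ValueError):
            sp.fisher_exact_2x2(t)


def fisher_enumeration_p(a, b, c, d):
    """Independent oracle: sum of hypergeometric table probabilities <= observed."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        p2 = comb(r1, a2) * comb(r2, c1 - a2) / denom
        if p2 <= p_obs * (1 + 1e-7):
            total += p2
    return min(total, 1.0)


class TestFisherEnumerationOracle:
    def test_all_tables_up_to_n12(self):
        for n in range(4, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        t = ContingencyTable([[a, b], [c, d]], ["r1", "r2"], ["c1", "c2"])
                        got = sp.fisher_exact_2x2(t).p_value
                        want = fisher_enumeration_p(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-7), (a, b, c, d)


class TestSpearman:
    def test_monotone_extremes(self):
        up = sp.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        down = sp.spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert up.rho == pytest.approx(1.0) and up.p_value == 0.0
        assert down.rho == pytest.approx(-1.0) and down.p_value == 0.0

    def test_rank_formula_case(self):
        # d = (-1, 1, -1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        res = sp.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        res = sp.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined


class TestBHAdjust:
    def test_step_up_hand_case(self):
        np.testing.assert_allclose(sp.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal_unchanged(self):
        np.testing.assert_allclose(sp.bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(sp.bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        adj = sp.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # step-up preserves the ranking of sorted raw p-values
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sp.bh_adjust([0.5, 1.2])


class TestScreenMarkers:
    def test_planted_markers_flagged(self, default_cohort):
        ft, ct, truth = default_cohort
        rep = sp.screen_markers(ft, ct).set_index("feature")
        flagged = rep.loc[truth.marker_feature_ids, "differential"]
        assert flagged.mean() >= 0.5  # markers enriched among the flags

    def test_constant_feature_not_flagged(self, default_cohort):
        ft, ct, _ = default_cohort
        values = ft.values.copy()
        values[:, 0] = 7.0
        ft2 = sp.FeatureTable(
            sample_ids=ft.sample_ids,
            feature_ids=ft.feature_ids,
            values=values,
            feature_meta=ft.feature_meta,
        )
        rep = sp.screen_markers(ft2, ct)
        assert not rep.iloc[0]["differential"]
        assert not rep.iloc[0]["count_pos"] and not rep.iloc[0]["count_neg"]

    def test_count_correlation_flags_positive_markers(self, default_cohort):
        ft, ct, truth = default_cohort
        rep = sp.screen_markers(ft, ct).set_index("feature")
        marker_rho = rep.loc[truth.marker_feature_ids, "rho_count"]
        assert marker_rho.median() > 0.2  # planted link is positive
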