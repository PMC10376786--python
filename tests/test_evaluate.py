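import numpy as np
import pytest
from scipy import stats

import seropanel as sp
from seropanel.evaluate import nested_loocv_probabilities

from test_products import table_from_values


class TestRocAndAuc:
    def test_probs_equal_labels_hits_corner(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        roc = sp.roc_curve(y.astype(float), y)
        corner = roc[(roc["sensitivity"] == 1) & (roc["specificity"] == 1)]
        assert len(corner) == 1

    def test_constant_probs_auc_half(self):
        y = np.array([0, 1] * 5)
        probs = np.full(10, 0.7)
        roc = sp.roc_curve(probs, y)
        assert len(roc) == 3  # sentinel, the value, sentinel
        assert sp.auc(probs, y) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_confusion_matrices_by_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.binomial(1, 0.5, 25)
        if y.sum() in (0, 25):
            pytest.skip("degenerate draw")
        probs = rng.uniform(size=25)
        roc = sp.roc_curve(probs, y)
        for _, row in roc.iterrows():
            pred = probs >= row["threshold"]
            tp = np.sum(pred & (y == 1))
            fn = np.sum(~pred & (y == 1))
            tn = np.sum(~pred & (y == 0))
            fp = np.sum(pred & (y == 0))
            assert row["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert row["specificity"] == pytest.approx(tn / (tn + fp))

    def test_roc_monotone(self):
        rng = np.random.default_rng(9)
        y = np.array([0, 1] * 10)
        roc = sp.roc_curve(rng.uniform(size=20), y)
        assert np.all(np.diff(roc["sensitivity"]) <= 1e-12)
        assert np.all(np.diff(roc["specificity"]) >= -1e-12)

    def test_perfect_and_antiperfect(self):
        y = np.array([0] * 5 + [1] * 5)
        assert sp.auc(np.linspace(0, 1, 10), y) == pytest.approx(1.0)
        assert sp.auc(np.linspace(1, 0, 10), y) == pytest.approx(0.0)

    def test_auc_equals_u_statistic(self):
        """Trapezoidal AUC is exactly U/(n1*n0), ties counted half."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n0 = rng.integers(3, 12, size=2)
            y = np.array([1] * n1 + [0] * n0)
            probs = rng.choice(np.linspace(0, 1, 7), size=n1 + n0)  # force ties
            u = stats.mannwhitneyu(
                probs[:n1], probs[n1:], alternative="two-sided"
            ).statistic
            assert sp.auc(probs, y) == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sp.roc_curve(np.array([0.2, 0.8]), np.array([1, 1]))


class TestOptimalThreshold:
    def test_perfect_separation(self):
        y = np.array([0] * 5 + [1] * 5)
        probs = np.array([0.1] * 5 + [0.9] * 5)
        thr, se, spc = sp.optimal_threshold(sp.roc_curve(probs, y))
        assert se == 1.0 and spc == 1.0
        assert 0.1 < thr <= 0.9

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.binomial(1, 0.5, 30)
        probs = rng.uniform(size=30)
        roc = sp.roc_curve(probs, y)
        thr, se, spc = sp.optimal_threshold(roc)
        sums = roc["sensitivity"] + roc["specificity"]
        assert se + spc == pytest.approx(sums.max())
        ties = roc[np.isclose(sums, sums.max())]
        assert thr == pytest.approx(ties["threshold"].min())

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.binomial(1, 0.5, 40)
        probs = rng.uniform(size=40)
        r1 = sp.roc_curve(probs, y)
        r2 = sp.roc_curve(probs**3, y)  # strictly monotone transform
        t1, se1, sp1 = sp.optimal_threshold(r1)
        t2, se2, sp2 = sp.optimal_threshold(r2)
        assert (se1, sp1) == (se2, sp2)


class TestLoocv:
    def make_separable(self, n=20, margin=5.0):
        rng = np.random.default_rng(0)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        x = rng.normal(size=n) + margin * y
        vals = np.exp(np.column_stack([x, rng.normal(size=n)]))
        return sp.expand_products(table_from_values(vals)), y.astype(float)

    def test_separable_data_orders_probs(self):
        table, y = self.make_separable()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probs = sp.loocv_probabilities(["F0"], table, y)
        assert probs[y == 1].min() > probs[y == 0].max()

    def test_deterministic(self, protein_expansion):
        exp, y = protein_expansion
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sp.fit_oplsda(exp, y)
            terms = sp.select_by_vip(m)[:2]
            p1 = sp.loocv_probabilities(terms, exp, y)
            p2 = sp.loocv_probabilities(terms, exp, y)
        np.testing.assert_array_equal(p1, p2)

    def test_permuted_labels_auc_near_half(self):
        """Fixed noise terms on permuted labels: LOOCV AUC hovers near 0.5."""
        import warnings

        rng = np.random.default_rng(1)
        aucs = []
        vals = rng.lognormal(size=(50, 3))
        table = sp.expand_products(table_from_values(vals))
        for _ in range(60):
            y = rng.permutation([0.0] * 25 + [1.0] * 25)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                probs = sp.loocv_probabilities(["F0", "F1"], table, y)
            aucs.append(sp.auc(probs, y))
        assert 0.3 < np.median(aucs) < 0.7

    def test_small_n_rejected(self):
        table, y = self.make_separable(n=8)
        with pytest.raises(ValueError):
            sp.loocv_probabilities(["F0"], table, y)


class TestEvaluatePanel:
    def test_planted_cohort_benchmark(self, default_cohort, protein_expansion):
        import warnings

        exp, y = protein_expansion
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sp.fit_oplsda(exp, y)
            cands = sp.select_by_vip(m)[:100]
            fit, _ = sp.stepwise_select(exp, cands, y)
            res = sp.evaluate_panel(fit.term_names[1:], exp, y)
        assert res.auc >= 0.8  # strong planted effects
        assert 0 <= res.threshold_star <= 1
        assert res.accuracy >= 0.7
        assert res.in_sample_accuracy >= res.accuracy - 0.1

    def test_metrics_round_trip(self, tmp_path, protein_expansion):
        import warnings

        exp, y = protein_expansion
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sp.fit_oplsda(exp, y)
            cands = sp.select_by_vip(m)[:50]
            fit, _ = sp.stepwise_select(exp, cands, y)
            res = sp.evaluate_panel(fit.term_names[1:], exp, y)
        import pandas as pd

        path = tmp_path / "metrics.csv"
        res.metrics_frame().to_csv(path, index=False)
        back = pd.read_csv(path)
        assert back["auc"][0] == pytest.approx(res.auc)
        assert back["threshold"][0] == pytest.approx(res.threshold_star)

    def test_nested_loocv_runs_and_is_deterministic(self):
        import warnings

        rng = np.random.default_rng(2)
        vals = rng.lognormal(size=(20, 4))
        table = table_from_values(vals)
        y = np.array([0.0, 1.0] * 10)

        def selector(sub, y_tr):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit, _ = sp.stepwise_select(sub, ["F0", "F1"], y_tr, max_terms=1)
            return fit.term_names[1:]

        exp = sp.expand_products(table)
        p1 = nested_loocv_probabilities(exp, y, selector)
        p2 = nested_loocv_probabilities(exp, y, selector)
        np.testing.assert_array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))
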