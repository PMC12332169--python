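import numpy as np
import pytest
from scipy import stats

from netmediator.io_formats import CASE, CONTROL, ExpressionMatrix
from netmediator.model_eval import (
    auroc,
    auprc,
    bootstrap_ci,
    cross_validate,
    delong_auc_variance,
    delong_test,
    f1_score,
)
from tests.conftest import make_expr


class TestAuroc:
    def test_pair_counting_example(self):
        scores = [0.9, 0.4, 0.5, 0.1]
        labels = [1, 1, 0, 0]
        assert auroc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auroc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_matches_explicit_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = 30
            y = (rng.uniform(size=n) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            s = rng.normal(size=n).round(1)  # rounding forces ties
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auroc(s, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = (rng.uniform(size=40) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        assert auroc(s, y) == pytest.approx(auroc(np.exp(2 * s), y))

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestBootstrapCI:
    def test_perfect_classifier_degenerate(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        assert bootstrap_ci(s, y, n_boot=200, seed=0) == (1.0, 1.0)

    def test_contains_point_estimate_usually(self):
        rng = np.random.default_rng(2)
        hits = 0
        trials = 50
        for i in range(trials):
            n = 60
            y = np.zeros(n, int)
            y[:25] = 1
            rng.shuffle(y)
            s = rng.normal(size=n) + 0.8 * y
            lo, hi = bootstrap_ci(s, y, n_boot=200, seed=i)
            if lo <= auroc(s, y) <= hi:
                hits += 1
        assert hits >= trials - 2

    def test_determinism(self):
        rng = np.random.default_rng(3)
        y = np.array([1, 0] * 15)
        s = rng.normal(size=30)
        assert bootstrap_ci(s, y, seed=5, n_boot=100) == bootstrap_ci(s, y, seed=5, n_boot=100)

    def test_nboot_validation(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1, 0], [1, 0], n_boot=10)


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=30)
        y = np.array([1, 0] * 15)
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_placement_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = np.array([1] * 12 + [0] * 18)
            rng.shuffle(y)
            s = rng.normal(size=30).round(1)
            a, _ = delong_auc_variance(s, y)
            assert a == pytest.approx(auroc(s, y), abs=1e-12)

    def test_variance_matches_jackknife(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = 40
            y = np.zeros(n, int)
            y[:15] = 1
            rng.shuffle(y)
            s = rng.normal(size=n) + 0.8 * y
            _, v = delong_auc_variance(s, y)
            ja = np.array([auroc(np.delete(s, i), np.delete(y, i)) for i in range(n)])
            vj = (n - 1) / n * ((ja - ja.mean()) ** 2).sum()
            assert abs(v - vj) / vj < 0.1

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        n = 50
        base = rng.normal(size=n)
        for _ in range(500):
            y = np.zeros(n, int)
            y[:20] = 1
            rng.shuffle(y)
            sa = base + rng.normal(0, 0.5, n)
            sb = base + rng.normal(0, 0.5, n)
            _, p = delong_test(sa, sb, y)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1


class TestCrossValidate:
    def _expr(self, n=60, n_genes=10, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n_genes, n))
        n_case = n // 3
        if informative:
            # first gene fully determines the label
            values[0, :] = -2.0
            values[0, :n_case] = 2.0
        return make_expr(values, n_case=n_case)

    def test_perfect_feature_tree_model(self):
        expr = self._expr(informative=True)
        out = cross_validate(expr, None, "rf", folds=3, seed=0)
        assert out["auroc"] == pytest.approx(1.0)

    def test_null_labels_auroc_band(self):
        expr = self._expr(informative=False, seed=8)
        out = cross_validate(expr, None, "extratrees", folds=3, seed=1)
        assert 0.35 <= out["auroc"] <= 0.65

    def test_same_seed_same_folds(self):
        expr = self._expr()
        a = cross_validate(expr, None, "rf", folds=3, seed=4)
        b = cross_validate(expr, None, "rf", folds=3, seed=4)
        assert (a["fold"] == b["fold"]).all()
        assert a["auroc"] == b["auroc"]

    def test_svm_runs(self):
        expr = self._expr()
        out = cross_validate(expr, None, "svm", folds=3, seed=0)
        assert out["auroc"] > 0.9

    def test_too_many_folds_stratification_error(self):
        expr = self._expr(n=12)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(expr, None, "rf", folds=10, seed=0)

    def test_unknown_panel_gene(self):
        expr = self._expr()
        with pytest.raises(ValueError, match="missing"):
            cross_validate(expr, ["nope"], "rf", folds=3, seed=0)


class TestOtherMetrics:
    def test_auprc_perfect(self):
        assert auprc([0.9, 0.8, 0.2], [1, 1, 0]) == pytest.approx(1.0)

    def test_f1_perfect(self):
        assert f1_score([0.9, 0.1], [1, 0]) == pytest.approx(1.0)
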