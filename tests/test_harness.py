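"""Classification harness: splits, Gaussian discriminants, forest, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from seedtax import harness as har
from seedtax import synthetic as syn
from seedtax.morphometrics import FEATURE_NAMES


def _table_from_xy(x, y):
    df = pd.DataFrame(x, columns=list(FEATURE_NAMES)[: x.shape[1]])
    for name in FEATURE_NAMES[x.shape[1]:]:
        df[name] = 0.0
    df = df[list(FEATURE_NAMES)]
    df[:] = np.column_stack([x, np.zeros((len(x), 6 - x.shape[1]))])
    df["class_id"] = y
    df["population_id"] = "p"
    return df


class TestSplitPerClass:
    def test_exact_quarters(self):
        table = _table_from_xy(np.zeros((200, 6)), np.repeat([0, 1], 100))
        plan = har.split_per_class(table, 0.75, rng_seed=1)
        y = table["class_id"].to_numpy()
        for cls in (0, 1):
            assert (y[plan.test_idx] == cls).sum() == 25
            assert (y[plan.train_idx] == cls).sum() == 75

    def test_ceiling_rounding_on_test_side(self):
        table = _table_from_xy(np.zeros((33, 6)), np.zeros(33, int))
        table.loc[0, "class_id"] = 1  # second class to satisfy validation
        table.loc[1, "class_id"] = 1
        plan = har.split_per_class(table, 0.75, rng_seed=0)
        y = table["class_id"].to_numpy()
        assert (y[plan.test_idx] == 0).sum() == 8  # ceil(31 * 0.25)
        table2 = _table_from_xy(np.zeros((37, 6)),
                                np.r_[np.zeros(33, int), np.ones(4, int)])
        plan2 = har.split_per_class(table2, 0.75, rng_seed=0)
        y2 = table2["class_id"].to_numpy()
        assert (y2[plan2.test_idx] == 0).sum() == 9  # ceil(33 * 0.25) = 9
        assert (y2[plan2.train_idx] == 0).sum() == 24

    def test_deterministic_and_disjoint(self):
        table = _table_from_xy(np.random.default_rng(0).random((60, 6)),
                               np.repeat([0, 1, 2], 20))
        p1 = har.split_per_class(table, rng_seed=9)
        p2 = har.split_per_class(table, rng_seed=9)
        assert np.array_equal(p1.train_idx, p2.train_idx)
        assert np.array_equal(p1.test_idx, p2.test_idx)
        assert len(np.union1d(p1.train_idx, p1.test_idx)) == 60

    def test_tiny_class_rejected(self):
        table = _table_from_xy(np.zeros((5, 6)), np.array([0, 0, 0, 0, 1]))
        with pytest.raises(ValueError):
            har.split_per_class(table, rng_seed=0)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(4)
    x = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(2, 1.5, (40, 3))])
    y = np.repeat([0, 1], 40)
    return x, y, har.fit_lda(x, y), har.fit_qda(x, y)


class TestGaussianDiscriminants:
    @pytest.mark.parametrize("kind", ["lda", "qda"])
    def test_posteriors_match_brute_force_density(self, fitted, kind):
        x, y, lda, qda = fitted
        model = lda if kind == "lda" else qda
        pts = np.random.default_rng(5).normal(1, 2, (50, 3))
        dens = np.column_stack([
            model.priors[k] * multivariate_normal(model.means[k],
                                                  model.covs[k]).pdf(pts)
            for k in range(2)
        ])
        expected = dens / dens.sum(axis=1, keepdims=True)
        assert np.abs(model.predict_proba(pts) - expected).max() < 1e-9

    def test_posterior_rows_sum_to_one(self, fitted):
        x, y, lda, qda = fitted
        pts = np.random.default_rng(6).normal(size=(30, 3))
        for model in (lda, qda):
            assert np.allclose(model.predict_proba(pts).sum(axis=1), 1.0)

    def test_symmetric_point_has_even_posterior(self):
        x = np.array([[0.0, 0], [0, 1], [0, -1], [4, 0], [4, 1], [4, -1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = har.fit_lda(x, y)
        p = model.predict_proba(np.array([[2.0, 0.0]]))[0]
        assert p[0] == pytest.approx(0.5, abs=1e-9)

    def test_equal_covariance_limit_lda_qda_agree(self):
        rng = np.random.default_rng(7)
        cov = np.array([[1.0, 0.3], [0.3, 0.8]])
        x = np.vstack([rng.multivariate_normal([0, 0], cov, 2000),
                       rng.multivariate_normal([2, 1], cov, 2000)])
        y = np.repeat([0, 1], 2000)
        lda, qda = har.fit_lda(x, y), har.fit_qda(x, y)
        gx, gy = np.meshgrid(np.linspace(-3, 5, 60), np.linspace(-3, 4, 60))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        agree = (lda.predict(grid) == qda.predict(grid)).mean()
        assert agree >= 0.99


class TestForest:
    def test_default_tree_count(self):
        rng = np.random.default_rng(0)
        model = har.fit_rdf(rng.random((40, 6)), np.repeat([0, 1], 20))
        assert len(model.estimators_) == 100

    def test_separable_data_high_accuracy(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.5, (100, 6)), rng.normal(5, 0.5, (100, 6))])
        y = np.repeat([0, 1], 100)
        model = har.fit_rdf(x[::2], y[::2], rng_seed=0)
        assert (model.predict(x[1::2]) == y[1::2]).mean() >= 0.95

    def test_invalid_estimator_count(self):
        with pytest.raises(ValueError):
            har.fit_rdf(np.zeros((4, 2)), np.array([0, 0, 1, 1]), n_estimators=0)


class TestRepetitions:
    def test_result_count_and_determinism(self, small_table):
        r1 = har.run_repetitions("lda", small_table, n_rep=5, base_seed=3)
        r2 = har.run_repetitions("lda", small_table, n_rep=5, base_seed=3)
        assert len(r1) == 5
        for a, b in zip(r1, r2):
            assert a.accuracy == b.accuracy
            assert np.array_equal(a.confusion, b.confusion)

    def test_perfectly_separated_classes_score_one(self):
        spec = syn.equal_covariance_feature_spec(4, separation=50.0, rng_seed=0)
        table = syn.sample_feature_table(spec, 20, rng_seed=0)
        for r in har.run_repetitions("qda", table, n_rep=3, base_seed=0):
            assert r.accuracy == 1.0

    def test_confusion_bookkeeping(self, small_table):
        results = har.run_repetitions("rdf", small_table, n_rep=2, base_seed=1)
        for r in results:
            assert r.confusion.sum() == 60  # 6 classes x ceil(40 * 0.25)
            assert r.accuracy == pytest.approx(
                np.trace(r.confusion) / r.confusion.sum())

    def test_unknown_method_rejected(self, small_table):
        with pytest.raises(ValueError):
            har.run_repetitions("svm", small_table, n_rep=1)


class TestAggregation:
    def test_rows_sum_to_hundred(self, small_table):
        results = har.run_repetitions("lda", small_table, n_rep=4, base_seed=0)
        agg = har.aggregate_confusion(results)
        assert np.allclose(agg.sum(axis=1), 100.0, atol=0.1)

    def test_pooled_matches_brute_force_recount(self, small_table):
        results = har.run_repetitions("lda", small_table, n_rep=4, base_seed=0)
        total = np.zeros_like(results[0].confusion, dtype=float)
        for r in results:
            total += r.confusion
        expected = 100 * total / total.sum(axis=1, keepdims=True)
        assert np.allclose(har.aggregate_confusion(results), expected)

    def test_perfect_classifier_has_diagonal_100(self):
        eye = np.eye(3, dtype=int) * 5
        results = [har.RepetitionResult(0, 1.0, eye)]
        agg = har.aggregate_confusion(results)
        assert np.allclose(np.diag(agg), 100.0)

    def test_summary_statistics(self):
        mk = lambda a: har.RepetitionResult(
            0, a, np.array([[int(10 * a), 10 - int(10 * a)], [0, 0]]))
        s = har.summarize_accuracy([mk(0.8), mk(1.0)], method="m")
        assert (s.min, s.max, s.mean, s.median) == (80.0, 100.0, 90.0, 90.0)
        s2 = har.summarize_accuracy([mk(0.9)] * 3, method="m")
        assert s2.mean == pytest.approx(90.0) and s2.sd == 0.0

    def test_summary_matches_reference_routine(self):
        rng = np.random.default_rng(8)
        accs = (rng.integers(0, 101, 50) / 100.0)
        results = [har.RepetitionResult(
            i, a, np.array([[round(100 * a), 100 - round(100 * a)], [0, 0]]))
            for i, a in enumerate(accs)]
        s = har.summarize_accuracy(results, "ref")
        assert s.mean == pytest.approx(100 * accs.mean(), abs=1e-9)
        assert s.median == pytest.approx(100 * np.median(accs), abs=1e-9)
        assert s.sd == pytest.approx(100 * np.std(accs, ddof=1), abs=1e-9)


class TestPermutationImportance:
    def test_informative_feature_dominates_and_noise_is_null(self):
        rng = np.random.default_rng(3)
        n = 400
        y = rng.integers(0, 2, n)
        x = rng.normal(size=(n, 6))
        x[:, 2] = y * 4.0 + rng.normal(0, 0.1, n)  # feature 2 determines class
        model = har.fit_lda(x, y)
        prof = har.permutation_importance(model, x, y, n_shuffles=10, rng_seed=0)
        assert np.argmax(prof.importances) == 2
        noise = np.delete(prof.importances, 2)
        assert np.abs(noise).max() <= 0.02

    def test_frozen_seed_reproduces_exactly(self, small_table):
        x, y = har.table_to_xy(small_table)
        model = har.fit_qda(x, y)
        p1 = har.permutation_importance(model, x, y, rng_seed=5)
        p2 = har.permutation_importance(model, x, y, rng_seed=5)
        assert np.array_equal(p1.importances, p2.importances)


class TestRocAuc:
    class _Scored:
        def __init__(self, proba, classes):
            self._p = proba
            self.classes = classes

        def predict_proba(self, x):
            return self._p

    def test_perfect_scores_reach_auc_one(self):
        y = np.repeat([0, 1, 2], 10)
        proba = np.eye(3)[y]
        model = self._Scored(proba, np.array([0, 1, 2]))
        for v in har.roc_auc_ovr(model, np.zeros((30, 1)), y).values():
            assert v["auc"] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 500
        y = rng.integers(0, 2, n)
        p1 = rng.random(n)
        proba = np.column_stack([1 - p1, p1])
        model = self._Scored(proba, np.array([0, 1]))
        aucs = har.roc_auc_ovr(model, np.zeros((n, 1)), y)
        assert abs(aucs[1]["auc"] - 0.5) < 0.05

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.integers(0, 2, n)
        s = rng.random(n) * 0.5 + y * rng.random(n) * 0.5
        for transform in (lambda v: v, np.sqrt, lambda v: v**3,
                          lambda v: 1 / (1 + np.exp(-5 * v))):
            proba = np.column_stack([1 - transform(s), transform(s)])
            model = self._Scored(proba, np.array([0, 1]))
            auc1 = har.roc_auc_ovr(model, np.zeros((n, 1)), y)[1]["auc"]
            if transform is not np.sqrt:
                base = auc1
            assert auc1 == pytest.approx(base, abs=1e-12)


class TestMethodOrderingProperties:
    def test_qda_beats_lda_under_class_specific_covariances(self):
        spec = syn.heteroscedastic_feature_spec(6, rng_seed=2)
        table = syn.sample_feature_table(spec, 60, rng_seed=1)
        lda = har.run_repetitions("lda", table, n_rep=20, base_seed=0)
        qda = har.run_repetitions("qda", table, n_rep=20, base_seed=0)
        assert (np.mean([r.accuracy for r in qda])
                >= np.mean([r.accuracy for r in lda]))

    def test_equal_covariances_make_qda_and_lda_equivalent(self):
        spec = syn.equal_covariance_feature_spec(6, separation=2.0, rng_seed=4)
        table = syn.sample_feature_table(spec, 250, rng_seed=2)
        lda = har.run_repetitions("lda", table, n_rep=20, base_seed=0)
        qda = har.run_repetitions("qda", table, n_rep=20, base_seed=0)
        gap = abs(np.mean([r.accuracy for r in qda])
                  - np.mean([r.accuracy for r in lda]))
        assert gap <= 0.02

    def test_accuracy_monotone_in_class_separation(self, library):
        base = None
        for sep in (0.0, 0.5, 1.0, 2.0):
            phenos = syn.make_phenotype_library(12, sep, 7)
            spec = syn.feature_spec_from_phenotypes(phenos, rel_sd=0.06)
            table = syn.sample_feature_table(spec, 30, rng_seed=11)
            res = har.run_repetitions("lda", table, n_rep=5, base_seed=0)
            mean = np.mean([r.accuracy for r in res])
            if base is not None:
                assert mean >= base - 0.02  # non-decreasing within noise
            base = mean
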