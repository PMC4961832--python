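import numpy as np
import pytest

from cancerlect.classify import (
    ContractError, EvaluationReport, GridConfig,
    cross_validate, evaluate_on_test, grid_search_svm,
    majority_learner, rf_learner, svm_learner,
    train_majority, train_rf, train_svm,
)
from cancerlect.dataset import FeatureTable
from cancerlect.preprocess import SmoteConfig


def separable_table(n_per_class=20, d=4, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(loc=0.0, size=(n_per_class, d)),
        rng.normal(loc=gap, size=(n_per_class, d)),
    ])
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    return FeatureTable([f"f{i}" for i in range(d)], X, labels)


def imbalanced_table(n_pos=178, n_neg=226, d=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, d))
    labels = np.array([1] * n_pos + [0] * n_neg)
    return FeatureTable([f"f{i}" for i in range(d)], X, labels)


class TestModels:
    def test_rf_memorizes_separable_toy(self):
        table = separable_table(10)
        model = train_rf(table, trees=50, seed=1)
        assert (model.predict(table) == table.labels).all()

    def test_rf_fixed_seed_is_deterministic(self):
        table = separable_table(10)
        p1 = train_rf(table, seed=3).predict(table)
        p2 = train_rf(table, seed=3).predict(table)
        np.testing.assert_array_equal(p1, p2)

    def test_predict_rejects_renamed_column(self):
        table = separable_table(5)
        model = train_rf(table, trees=10, seed=1)
        renamed = FeatureTable(["f0", "f1", "f2", "zzz"], table.X, table.labels)
        with pytest.raises(ContractError):
            model.predict(renamed)

    def test_svm_training_accuracy_on_separable_toy(self):
        table = separable_table(10)
        model = train_svm(table, c=8.0, g=0.1)
        assert (model.predict(table) == table.labels).all()

    def test_svm_default_gamma_is_one_over_d(caplog_=None):
        table = separable_table(5, d=4)
        model = train_svm(table)
        assert model.params["g"] == pytest.approx(1 / 4)

    def test_svm_decision_values_deterministic(self):
        table = separable_table(8)
        m1 = train_svm(table, c=2.0, g=0.5)
        m2 = train_svm(table, c=2.0, g=0.5)
        np.testing.assert_array_equal(
            m1.estimator.decision_function(table.X),
            m2.estimator.decision_function(table.X),
        )

    def test_single_class_training_errors(self):
        X = np.zeros((5, 2))
        table = FeatureTable(["a", "b"], X, np.array([1] * 5))
        with pytest.raises(ValueError):
            train_svm(table)
        with pytest.raises(ValueError):
            train_rf(table)


class TestGridSearch:
    def test_default_grid_evaluates_110_pairs(self):
        table = separable_table(8, d=2)
        result = grid_search_svm(table, GridConfig(folds=4, seed=1))
        assert len(result.surface) == 11 * 10
        assert result.cv_accuracy == max(result.surface.values())

    def test_tie_broken_toward_smaller_c_then_g(self):
        table = separable_table(10, d=2, gap=10.0)
        result = grid_search_svm(table, GridConfig(folds=4, seed=1))
        best_acc = result.cv_accuracy
        winners = [k for k, v in result.surface.items() if v == best_acc]
        assert min(winners) == (
            int(np.log2(result.best_c)), int(np.log2(result.best_g))
        )

    def test_two_gaussian_toy_reaches_high_accuracy(self):
        table = separable_table(25, d=3, gap=6.0, seed=2)
        result = grid_search_svm(table, GridConfig(folds=5, seed=1))
        assert result.cv_accuracy >= 0.95

    def test_singleton_grid_equals_direct_cv(self):
        table = separable_table(12, d=2, seed=3)
        grid = GridConfig(c_exponents=(1,), g_exponents=(-3,), folds=4, seed=5)
        result = grid_search_svm(table, grid)
        direct = cross_validate(table, svm_learner(c=2.0, g=2.0**-3), k=4, seed=5)
        assert result.cv_accuracy == pytest.approx(direct.accuracy)


class TestCrossValidation:
    def test_every_row_evaluated_exactly_once(self):
        table = separable_table(15)
        report = cross_validate(table, rf_learner(trees=20, seed=1), k=5, seed=1)
        assert report.total == table.n

    def test_majority_baseline_accuracy_is_exact_class_fraction(self):
        table = imbalanced_table()
        report = cross_validate(table, majority_learner(), k=10, seed=1)
        assert report.accuracy == pytest.approx(226 / 404, abs=1e-12)
        assert round(100 * report.accuracy, 4) == 55.9406

    def test_stratification_keeps_fold_fractions_close(self):
        from sklearn.model_selection import StratifiedKFold

        table = imbalanced_table()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=1)
        global_frac = table.labels.mean()
        for _, test_idx in skf.split(table.X, table.labels):
            fold_pos = table.labels[test_idx].sum()
            assert abs(fold_pos - global_frac * len(test_idx)) <= 1.0

    def test_balancing_in_folds_does_not_change_evaluated_rows(self):
        table = imbalanced_table(60, 80)
        balanced = cross_validate(
            table, rf_learner(trees=10, seed=1), k=5, seed=1,
            balance=SmoteConfig(rate=100, k_neighbors=3, seed=2),
        )
        plain = cross_validate(table, rf_learner(trees=10, seed=1), k=5, seed=1)
        assert balanced.total == plain.total == table.n

    def test_small_class_errors(self):
        table = imbalanced_table(5, 50)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(table, majority_learner(), k=10)


class TestEvaluation:
    def test_metric_identities_recompute_from_counts(self):
        report = EvaluationReport(tp=12, tn=18, fp=4, fn=6, protocol="supplied-test-set")
        assert report.total == 40
        assert report.accuracy == pytest.approx((12 + 18) / 40, abs=1e-12)
        assert report.accuracy == pytest.approx(0.75)
        assert report.sensitivity == pytest.approx(12 / 18, abs=1e-12)
        assert report.specificity == pytest.approx(18 / 22, abs=1e-12)
        mcc_direct = (12 * 18 - 4 * 6) / np.sqrt((12 + 4) * (12 + 6) * (18 + 4) * (18 + 6))
        assert report.mcc == pytest.approx(mcc_direct, abs=1e-12)

    def test_perfect_model_on_test_set(self):
        table = separable_table(10)
        model = train_rf(table, trees=30, seed=1)
        report = evaluate_on_test(model, table)
        assert report.tp + report.tn == table.n
        assert report.accuracy == 1.0

    def test_constant_positive_predictor_on_balanced_test(self):
        X = np.zeros((40, 2))
        train = FeatureTable(["a", "b"], X, np.array([1] * 30 + [0] * 10))
        model = train_majority(train)  # majority is positive here
        test = FeatureTable(["a", "b"], np.zeros((40, 2)), np.array([1] * 20 + [0] * 20))
        report = evaluate_on_test(model, test)
        assert report.accuracy == 0.5

    def test_unlabelled_test_set_rejected(self):
        table = separable_table(5)
        model = train_rf(table, trees=10, seed=1)
        unlabelled = FeatureTable(list(table.feature_names), table.X)
        with pytest.raises(ValueError, match="labelled"):
            evaluate_on_test(model, unlabelled)
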