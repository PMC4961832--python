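"""Random-forest and RBF-SVM training, grid search, and evaluation.

Two evaluation protocols mirror the workbench conventions the pipeline
emulates: stratified k-fold cross-validation with confusion counts pooled
over folds (so accuracy has an exact n denominator), and a supplied test
set scored by a model trained on the full training table. Class balancing,
when requested, is applied inside each training fold only — evaluation
folds and supplied test sets are never resampled.

Defaults: random forest with 100 trees and floor(log2 d) + 1 candidate
features per split; SVM grid search over c = 2^i (i = -5..15 step 2) and
g = 2^j (j = -15..3 step 2) scored by stratified 5-fold CV, ties broken
toward smaller c then smaller g. An SVM trained without an explicit g uses
g = 1/d (d = number of features), which is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import FeatureTable
from .preprocess import SmoteConfig, smote

logger = logging.getLogger(__name__)


class ContractError(ValueError):
    """Prediction-time feature names do not match the training table."""


@dataclass
class Model:
    """A fitted classifier bound to the feature names it was trained on."""

    estimator: object
    feature_names: list[str]
    kind: str
    params: dict

    def predict(self, table: FeatureTable) -> np.ndarray:
        if list(table.feature_names) != self.feature_names:
            raise ContractError(
                "feature names at predict time differ from training time; "
                "extract the same descriptor families in the same order"
            )
        return np.asarray(self.estimator.predict(table.X), dtype=int)


Learner = Callable[[FeatureTable], Model]


@dataclass
class EvaluationReport:
    """Pooled confusion counts and the metrics derived from them."""

    tp: int
    tn: int
    fp: int
    fn: int
    protocol: str

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else 0.0

    @property
    def mcc(self) -> float:
        denom = math.sqrt(
            (self.tp + self.fp) * (self.tp + self.fn) * (self.tn + self.fp) * (self.tn + self.fn)
        )
        return (self.tp * self.tn - self.fp * self.fn) / denom if denom else 0.0

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray, protocol: str) -> "EvaluationReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            protocol=protocol,
        )

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "total": self.total,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }


def _check_labelled(table: FeatureTable) -> None:
    if table.labels is None:
        raise ValueError("a labelled table is required")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("both classes must be present")


# ---------------------------------------------------------------------------
# learners

def train_rf(table: FeatureTable, trees: int = 100, seed: int = 1) -> Model:
    """Bagged decision-tree ensemble with floor(log2 d)+1 features per split."""
    _check_labelled(table)
    if table.n < 2:
        raise ValueError("need >= 2 rows to train")
    max_features = min(int(math.floor(math.log2(table.d))) + 1, table.d)
    est = RandomForestClassifier(
        n_estimators=trees, max_features=max_features, random_state=seed
    )
    est.fit(table.X, table.labels)
    return Model(est, list(table.feature_names), "rf", {"trees": trees, "seed": seed})


def train_svm(table: FeatureTable, c: float = 1.0, g: Optional[float] = None) -> Model:
    """RBF-kernel SVM; when g is unspecified, g = 1/d is used and logged."""
    _check_labelled(table)
    if c <= 0:
        raise ValueError("c must be > 0")
    if g is None:
        g = 1.0 / table.d
        logger.info("train_svm: g unspecified, using 1/d = %.6g", g)
    elif g <= 0:
        raise ValueError("g must be > 0")
    est = SVC(C=c, gamma=g, kernel="rbf")
    est.fit(table.X, table.labels)
    return Model(est, list(table.feature_names), "svm", {"c": c, "g": g})


def train_majority(table: FeatureTable) -> Model:
    """Constant-prediction baseline: the training majority class (tie -> negative)."""
    if table.labels is None:
        raise ValueError("a labelled table is required")
    counts = np.bincount(table.labels, minlength=2)
    label = int(counts[1] > counts[0])

    class _Const:
        def predict(self, X):
            return np.full(X.shape[0], label, dtype=int)

    return Model(_Const(), list(table.feature_names), "majority", {"label": label})


def rf_learner(trees: int = 100, seed: int = 1) -> Learner:
    return lambda table: train_rf(table, trees=trees, seed=seed)


def svm_learner(c: float = 1.0, g: Optional[float] = None) -> Learner:
    return lambda table: train_svm(table, c=c, g=g)


def majority_learner() -> Learner:
    return train_majority


# ---------------------------------------------------------------------------
# grid search

@dataclass(frozen=True)
class GridConfig:
    c_exponents: tuple[int, ...] = tuple(range(-5, 16, 2))
    g_exponents: tuple[int, ...] = tuple(range(-15, 4, 2))
    folds: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.c_exponents or not self.g_exponents:
            raise ValueError("exponent sets must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class GridResult:
    best_c: float
    best_g: float
    cv_accuracy: float
    surface: dict[tuple[int, int], float] = field(default_factory=dict)


def grid_search_svm(table: FeatureTable, grid: GridConfig = GridConfig()) -> GridResult:
    """Exhaustive (c, g) search on a log2 grid, scored by pooled stratified
    CV accuracy; ties broken by smaller c, then smaller g."""
    _check_labelled(table)
    counts = np.bincount(table.labels, minlength=2)
    if counts.min() < grid.folds:
        raise ValueError(
            f"each class needs >= folds={grid.folds} rows (have {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    splits = list(skf.split(table.X, table.labels))
    surface: dict[tuple[int, int], float] = {}
    best: Optional[tuple[float, int, int]] = None
    for i in sorted(grid.c_exponents):
        for j in sorted(grid.g_exponents):
            c, g = 2.0**i, 2.0**j
            correct = 0
            for train_idx, test_idx in splits:
                est = SVC(C=c, gamma=g, kernel="rbf")
                est.fit(table.X[train_idx], table.labels[train_idx])
                correct += int((est.predict(table.X[test_idx]) == table.labels[test_idx]).sum())
            acc = correct / table.n
            surface[(i, j)] = acc
            if best is None or acc > best[0] + 1e-12:
                best = (acc, i, j)
    assert best is not None
    acc, i, j = best
    return GridResult(best_c=2.0**i, best_g=2.0**j, cv_accuracy=acc, surface=surface)


# ---------------------------------------------------------------------------
# evaluation protocols

def cross_validate(
    table: FeatureTable,
    learner: Learner,
    k: int = 10,
    seed: int = 1,
    balance: Optional[SmoteConfig] = None,
) -> EvaluationReport:
    """Stratified k-fold CV with pooled confusion counts.

    Optional SMOTE is applied to the training part of each fold only, so
    every original row is evaluated exactly once and the evaluated-row count
    is unaffected by balancing.
    """
    _check_labelled(table)
    counts = np.bincount(table.labels, minlength=2)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} rows < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_true = np.empty(table.n, dtype=int)
    y_pred = np.empty(table.n, dtype=int)
    for train_idx, test_idx in skf.split(table.X, table.labels):
        train = FeatureTable(
            list(table.feature_names), table.X[train_idx], table.labels[train_idx]
        )
        if balance is not None:
            train = smote(train, balance)
        model = learner(train)
        test = FeatureTable(
            list(table.feature_names), table.X[test_idx], table.labels[test_idx]
        )
        y_true[test_idx] = table.labels[test_idx]
        y_pred[test_idx] = model.predict(test)
    return EvaluationReport.from_predictions(y_true, y_pred, protocol=f"cross-validation k={k}")


def evaluate_on_test(model: Model, test: FeatureTable) -> EvaluationReport:
    """Score a fitted model on a labelled supplied test set."""
    if test.labels is None:
        raise ValueError("supplied test set must be labelled; use Model.predict for unlabelled data")
    y_pred = model.predict(test)
    return EvaluationReport.from_predictions(test.labels, y_pred, protocol="supplied-test-set")
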