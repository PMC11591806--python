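"""Ensemble classification (NB + KNN + SVM, majority vote) and evaluation.

The ensemble trains a Gaussian naive Bayes model, a k-nearest-neighbour
classifier (Euclidean) and an RBF-kernel support vector machine on the
same table and predicts by majority vote; with three voters over two
classes no tie can occur (the configurable tie order covers hypothetical
even ensembles).

Evaluation follows the standard confusion-matrix metrics with malignant
as the positive class: precision TP/(TP+FP), recall TP/(TP+FN), accuracy
(TP+TN)/total, error 1-accuracy, F1 = 2PR/(P+R).  Percentages are
truncated (not rounded) to three decimals.  Cross-validation is
stratified; per fold the full pipeline (fit normalization on the training
fold, information-gain selection, CORT rejection, ensemble training) runs
with no test-fold leakage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import cort as cort_mod
from . import preprocess
from .config import ECMConfig, PipelineConfig
from .data_io import MALIGNANT, LabeledTable

logger = logging.getLogger(__name__)


@dataclass
class EnsembleModel:
    """Three fitted base classifiers plus the tie-resolution order."""

    classifiers: dict[str, Any]
    tie_order: tuple[str, ...]
    feature_count: int


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    def to_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


def truncate_percent(fraction: float, decimals: int = 3) -> float:
    """A fraction as a percentage truncated (not rounded) to ``decimals``."""
    scale = 10 ** decimals
    return math.floor(fraction * 100.0 * scale + 1e-9) / scale


@dataclass
class MetricsReport:
    """The five confusion-matrix metrics, as fractions in [0, 1]."""

    precision: float
    recall: float
    accuracy: float
    error: float
    f1: float
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            name: {"fraction": getattr(self, name),
                   "percent": truncate_percent(getattr(self, name))}
            for name in ("precision", "recall", "accuracy", "error", "f1")
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.to_dict()
        return d


@dataclass
class CVReport:
    """Per-fold metrics, their arithmetic mean and the fold assignment."""

    folds: list[MetricsReport]
    mean: MetricsReport
    fold_assignment: np.ndarray
    seed: int
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_folds": len(self.folds),
            "folds": [m.to_dict() for m in self.folds],
            "mean": self.mean.to_dict(),
            **self.extras,
        }


def train_ecm(train: LabeledTable, config: ECMConfig | None = None) -> EnsembleModel:
    """Fit the three base classifiers on the same training table."""
    config = config or ECMConfig()
    config.validate()
    if len(set(train.labels)) < 2:
        raise ValueError("ensemble training needs at least two classes")
    if train.n <= config.knn_k:
        raise ValueError(f"need more than knn_k={config.knn_k} training instances")
    y = train.labels.astype(str)
    classifiers = {
        "nb": GaussianNB(),
        "knn": KNeighborsClassifier(n_neighbors=config.knn_k),
        "svm": SVC(kernel=config.svm_kernel, C=config.svm_c),
    }
    for clf in classifiers.values():
        clf.fit(train.values, y)
    return EnsembleModel(classifiers, tuple(config.tie_order), train.b)


def predict_ecm(model: EnsembleModel, table: LabeledTable) -> np.ndarray:
    """Majority vote of the base predictions, per instance.

    If a vote ever ties (impossible for three voters on two classes), the
    label predicted by the earliest classifier in the tie order among the
    tied labels wins.
    """
    if table.b != model.feature_count:
        raise ValueError(
            f"feature count mismatch: table has {table.b}, model expects {model.feature_count}"
        )
    votes = {name: clf.predict(table.values) for name, clf in model.classifiers.items()}
    stacked = np.stack([votes[name] for name in model.tie_order])
    out = np.empty(table.n, dtype=object)
    for i in range(table.n):
        labels, counts = np.unique(stacked[:, i], return_counts=True)
        winners = labels[counts == counts.max()]
        if len(winners) == 1:
            out[i] = winners[0]
        else:
            for name in model.tie_order:
                if votes[name][i] in winners:
                    out[i] = votes[name][i]
                    break
    return out


def confusion(y_true: np.ndarray, y_pred: np.ndarray,
              positive_label: str = MALIGNANT) -> ConfusionMatrix:
    """Tally the confusion counts with ``positive_label`` as positive."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def f1_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The five metrics from a confusion matrix (0 on empty denominators)."""
    if cm.total == 0:
        raise ValueError("confusion matrix must count at least one instance")
    if cm.tp + cm.fp == 0:
        logger.warning("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        logger.warning("no positive instances; recall defined as 0")
        recall = 0.0
    else:
        recall = cm.tp / (cm.tp + cm.fn)
    accuracy = (cm.tp + cm.tn) / cm.total
    return MetricsReport(precision, recall, accuracy, 1.0 - accuracy,
                         f1_measure(precision, recall), cm)


def mean_metrics(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of per-fold metrics (confusion counts summed)."""
    cms = [r.confusion for r in reports if r.confusion is not None]
    total_cm = sum(cms[1:], cms[0]) if cms else None
    return MetricsReport(
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        error=float(np.mean([r.error for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        confusion=total_cm,
    )


def cross_validate(table: LabeledTable, config: PipelineConfig | None = None,
                   run_cort: bool = True) -> CVReport:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold: min-max normalization fit on the training fold, information
    gain feature selection on the training fold, CORT rejection of the
    training fold, ensemble training on the kept instances, prediction of
    the test fold.  ``run_cort=False`` skips the rejection stage (used to
    evaluate the preprocessing and ensemble in isolation).
    """
    config = (config or PipelineConfig()).validate()
    y = table.labels.astype(str)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError("every class needs at least cv_folds instances to stratify")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    fold_assignment = np.empty(table.n, dtype=int)
    fold_reports: list[MetricsReport] = []
    extras: dict[str, Any] = {"stages": []}
    for fold, (train_idx, test_idx) in enumerate(skf.split(table.values, y)):
        fold_assignment[test_idx] = fold
        train = table.subset_rows(train_idx)
        test = table.subset_rows(test_idx)
        stage: dict[str, Any] = {"fold": fold, "n_train": train.n, "n_test": test.n}

        if config.normalize:
            mm = preprocess.fit_minmax(train)
            train = preprocess.apply_minmax(mm, train)
            test = preprocess.apply_minmax(mm, test)

        ranking = preprocess.select_features(train, config.ig)
        train = train.subset_features(ranking.selected)
        test = test.subset_features(ranking.selected)
        stage["features"] = [table.feature_names[i] for i in ranking.selected]

        if run_cort:
            cort_result = cort_mod.cort_reject(train, config, seed=config.seed + fold)
            stage.update(tm=cort_result.tm, out=cort_result.out,
                         rest=cort_result.rest, ins=cort_result.ins)
            train = train.subset_rows(cort_result.kept)

        model = train_ecm(train, config.ecm)
        y_pred = predict_ecm(model, test)
        fold_reports.append(metrics(confusion(test.labels, y_pred)))
        extras["stages"].append(stage)

    return CVReport(fold_reports, mean_metrics(fold_reports), fold_assignment,
                    config.seed, extras)
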