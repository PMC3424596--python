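"""Leave-one-subject-out evaluation of three tree-based classifiers.

Every window of one subject is held out per fold; the remaining subjects'
windows train the model, so no within-subject leakage occurs.  Three
classifiers are compared:

* ``c45`` — an entropy-split decision tree (information-gain splits, the
  C4.5 family) via :class:`sklearn.tree.DecisionTreeClassifier`;
* ``regression_tree`` — classification via regression: one regression tree
  per class fitted to 0/1 indicator targets, predicting the argmax class;
* ``random_forest`` — a 100-tree :class:`sklearn.ensemble.RandomForestClassifier`.

Metrics use "attention" as the positive class: per-fold accuracy
``(TP+TN)/total``, sensitivity ``TP/(TP+FN)``, specificity ``TN/(TN+FP)``;
report averages are unweighted means over folds (a window-count-weighted
variant is available).  Undefined per-fold metrics (a fold with no positive
windows) are excluded from the mean with a warning.

NA feature sentinels are imputed with the training fold's per-feature median
(test folds never influence the imputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .io import ATTENTION, NONATTENTION, FeatureTable, ValidationError

__all__ = [
    "CLASSIFIER_NAMES",
    "FoldResult",
    "EvaluationReport",
    "loso_folds",
    "fit_predict",
    "summarize",
    "evaluate_loso",
]

CLASSIFIER_NAMES = ("c45", "regression_tree", "random_forest")

#: Row/column order of the confusion matrix (true × predicted).
CONFUSION_LABELS = (ATTENTION, NONATTENTION)


@dataclass
class FoldResult:
    """Confusion matrix for one held-out subject under one classifier.

    ``confusion[i, j]`` counts windows with true label ``CONFUSION_LABELS[i]``
    predicted as ``CONFUSION_LABELS[j]``; entries sum to the held-out
    subject's window count.
    """

    held_out_subject: str
    classifier_name: str
    confusion: np.ndarray

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.shape != (2, 2) or (self.confusion < 0).any():
            raise ValidationError("confusion must be a 2x2 nonnegative matrix")
        if self.classifier_name not in CLASSIFIER_NAMES:
            raise ValidationError(f"unknown classifier {self.classifier_name!r}")

    @property
    def tp(self) -> int:
        return int(self.confusion[0, 0])

    @property
    def fn(self) -> int:
        return int(self.confusion[0, 1])

    @property
    def fp(self) -> int:
        return int(self.confusion[1, 0])

    @property
    def tn(self) -> int:
        return int(self.confusion[1, 1])

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


@dataclass
class EvaluationReport:
    """Per-fold results plus per-classifier metric averages (fractions)."""

    per_fold: list[FoldResult]
    averages: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self, percent: bool = True) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "averages": {
                clf: {k: v * scale for k, v in metrics.items()}
                for clf, metrics in self.averages.items()
            },
            "per_fold": [
                {
                    "subject": f.held_out_subject,
                    "classifier": f.classifier_name,
                    "confusion": f.confusion.tolist(),
                    "accuracy": f.accuracy * scale,
                    "sensitivity": f.sensitivity * scale,
                    "specificity": f.specificity * scale,
                }
                for f in self.per_fold
            ],
        }


def loso_folds(table: FeatureTable) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """One (train, test) split per subject, covering each exactly once."""
    frame = table.frame
    subjects = table.subjects
    if len(subjects) < 2:
        raise ValidationError(
            f"leave-one-subject-out needs >= 2 subjects, got {len(subjects)}"
        )
    for subj, group in frame.groupby("subject_id"):
        present = set(group["label"])
        if present != set(CONFUSION_LABELS):
            warnings.warn(
                f"subject {subj} lacks rows for labels "
                f"{sorted(set(CONFUSION_LABELS) - present)}",
                stacklevel=2,
            )
    folds = []
    for subj in subjects:
        mask = frame["subject_id"] == subj
        folds.append((frame[~mask], frame[mask]))
    return folds


class _RegressionTreeClassifier:
    """Classification via regression trees on indicator-encoded targets."""

    def __init__(self, classes: tuple[str, ...], random_state: int, max_depth=None):
        self.classes = classes
        self.trees = [
            DecisionTreeRegressor(random_state=random_state + i, max_depth=max_depth)
            for i, _ in enumerate(classes)
        ]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RegressionTreeClassifier":
        for cls, tree in zip(self.classes, self.trees):
            tree.fit(X, (y == cls).astype(float))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.column_stack([t.predict(X) for t in self.trees])
        return np.asarray(self.classes)[scores.argmax(axis=1)]


def _make_classifier(name: str, seed: int, rf_n_estimators: int, max_depth):
    if name == "c45":
        return DecisionTreeClassifier(
            criterion="entropy", random_state=seed, max_depth=max_depth
        )
    if name == "regression_tree":
        return _RegressionTreeClassifier(
            CONFUSION_LABELS, random_state=seed, max_depth=max_depth
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=rf_n_estimators, random_state=seed, max_depth=max_depth
        )
    raise ValidationError(
        f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}"
    )


def _impute_train_median(
    train: pd.DataFrame, test: pd.DataFrame, feature_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    Xtr = train[feature_names].to_numpy(dtype=float)
    Xte = test[feature_names].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(Xtr, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    for X in (Xtr, Xte):
        idx = np.where(~np.isfinite(X))
        X[idx] = med[idx[1]]
    return Xtr, Xte


def fit_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    classifier_name: str,
    seed: int = 0,
    rf_n_estimators: int = 100,
    max_depth: int | None = None,
) -> FoldResult:
    """Fit one classifier on the training rows and tabulate the test fold."""
    feature_names = [c for c in train.columns if c not in ("subject_id", "window_index", "label")]
    ytr = train["label"].to_numpy()
    if len(set(ytr)) < 2:
        raise ValidationError("training data must contain both classes")
    Xtr, Xte = _impute_train_median(train, test, feature_names)
    model = _make_classifier(classifier_name, seed, rf_n_estimators, max_depth)
    model.fit(Xtr, ytr)
    pred = np.asarray(model.predict(Xte))
    yte = test["label"].to_numpy()
    confusion = np.zeros((2, 2), dtype=int)
    for i, true_label in enumerate(CONFUSION_LABELS):
        for j, pred_label in enumerate(CONFUSION_LABELS):
            confusion[i, j] = int(np.sum((yte == true_label) & (pred == pred_label)))
    subjects = set(test["subject_id"])
    held_out = subjects.pop() if len(subjects) == 1 else ",".join(sorted(subjects))
    return FoldResult(
        held_out_subject=held_out, classifier_name=classifier_name, confusion=confusion
    )


def summarize(per_fold: list[FoldResult], weighted: bool = False) -> EvaluationReport:
    """Average per-fold metrics into a Table-style report.

    ``weighted=True`` weights folds by window count instead of uniformly.
    """
    if not per_fold:
        raise ValidationError("no folds to summarize")
    averages: dict[str, dict[str, float]] = {}
    for clf in dict.fromkeys(f.classifier_name for f in per_fold):
        folds = [f for f in per_fold if f.classifier_name == clf]
        metrics: dict[str, float] = {}
        for metric in ("accuracy", "specificity", "sensitivity"):
            vals = np.array([getattr(f, metric) for f in folds], dtype=float)
            wts = np.array([f.n for f in folds], dtype=float) if weighted else np.ones(len(folds))
            ok = np.isfinite(vals)
            if not ok.all():
                bad = [f.held_out_subject for f, o in zip(folds, ok) if not o]
                warnings.warn(
                    f"{clf}: {metric} undefined for folds {bad}; excluded from mean",
                    stacklevel=2,
                )
            if not ok.any():
                metrics[metric] = float("nan")
            else:
                metrics[metric] = float(np.average(vals[ok], weights=wts[ok]))
        averages[clf] = metrics
    return EvaluationReport(per_fold=per_fold, averages=averages)


def evaluate_loso(
    table: FeatureTable,
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    seed: int = 0,
    rf_n_estimators: int = 100,
    max_depth: int | None = None,
    weighted: bool = False,
) -> EvaluationReport:
    """Full leave-one-subject-out evaluation of the named classifiers."""
    folds = loso_folds(table)
    results = [
        fit_predict(tr, te, clf, seed=seed, rf_n_estimators=rf_n_estimators, max_depth=max_depth)
        for clf in classifiers
        for tr, te in folds
    ]
    return summarize(results, weighted=weighted)
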