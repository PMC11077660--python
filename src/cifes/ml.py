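"""Gait-feature machine learning: the 8-D bilateral feature matrix, the
median-Gaussian-kernel SVM with stratified 10-fold cross-validation, and the
day-over-day discriminability trend used to track rehabilitation.

The kernel length scale follows the median heuristic: with standardized
training rows, gamma = 1 / (2 * median(pairwise Euclidean distance)^2).
Standardization and the median are computed per fold on training data only,
so validation rows never leak into the kernel scale.  As a patient's gait
statistics converge toward the healthy reference over treatment sessions,
the patient-vs-healthy cross-validated accuracy decays toward chance — the
rehabilitation signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from cifes.io import log
from cifes.kinematics import GaitCycleFeatures

__all__ = ["FEATURE_COLUMNS", "FeatureMatrix", "CVReport", "MedianGaussianSVC",
           "build_features", "crossval_svm", "rehab_trend"]

#: fixed column order of the 8-D bilateral feature matrix
FEATURE_COLUMNS = (
    "left_maxaa", "left_minaa", "left_max_ang_vel", "left_gcd",
    "right_maxaa", "right_minaa", "right_max_ang_vel", "right_gcd",
)


@dataclass
class FeatureMatrix:
    """Rows of matched left/right cycle pairs, 8 features per row."""

    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_COLUMNS):
            raise ValueError(f"feature matrix must have {len(FEATURE_COLUMNS)} columns")
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("labels must match row count")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing values")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.X, columns=list(FEATURE_COLUMNS))
        df["label"] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df) -> "FeatureMatrix":
        expected = list(FEATURE_COLUMNS) + ["label"]
        if list(df.columns) != expected:
            raise ValueError(
                f"feature matrix schema mismatch: expected columns {expected}, "
                f"got {list(df.columns)}")
        return cls(df[list(FEATURE_COLUMNS)].to_numpy(dtype=float),
                   df["label"].to_numpy())

    def relabeled(self, label: str) -> "FeatureMatrix":
        return FeatureMatrix(self.X.copy(), np.full(len(self), label, dtype=object))

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        return FeatureMatrix(np.vstack([p.X for p in parts]),
                             np.concatenate([p.labels for p in parts]))


@dataclass
class CVReport:
    accuracy: float
    fold_accuracies: np.ndarray
    confusion: np.ndarray
    classes: np.ndarray
    #: per-class one-vs-rest ROC points: {class: (fpr, tpr)}
    roc: dict = field(default_factory=dict)


def build_features(left: list[GaitCycleFeatures], right: list[GaitCycleFeatures],
                   label: str) -> FeatureMatrix:
    """Assemble the 8-D matrix by pairing left/right cycles on cycle_index.

    Unpaired trailing cycles are dropped (count logged).
    """
    if not left or not right:
        raise ValueError("build_features requires non-empty cycle sequences")
    li = {f.cycle_index: f for f in left}
    ri = {f.cycle_index: f for f in right}
    common = sorted(set(li) & set(ri))
    dropped = len(left) + len(right) - 2 * len(common)
    if dropped:
        log(f"build_features: dropped {dropped} unpaired cycle(s)")
    if not common:
        raise ValueError("no left/right cycle pairs share a cycle_index")
    rows = [[li[i].maxaa, li[i].minaa, li[i].max_ang_vel, li[i].gcd,
             ri[i].maxaa, ri[i].minaa, ri[i].max_ang_vel, ri[i].gcd]
            for i in common]
    return FeatureMatrix(np.array(rows), np.full(len(common), label, dtype=object))


class MedianGaussianSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with the median-heuristic length scale.

    ``fit`` standardizes the training rows, sets
    ``gamma = 1 / (2 * median(pdist(X_std))**2)`` and trains an ``SVC``.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        d = pdist(Xs)
        med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
        self.gamma_ = 1.0 / (2.0 * med * med)
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma_,
                        decision_function_shape="ovr").fit(Xs, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))

    def decision_function(self, X):
        return self.svc_.decision_function(
            self.scaler_.transform(np.asarray(X, dtype=float)))


def crossval_svm(fm: FeatureMatrix, folds: int = 10, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation of the median-Gaussian SVM.

    Standardization and the median heuristic are recomputed inside each
    fold on its training rows only.  Accuracy is the average of the
    per-fold validation accuracies; the confusion matrix pools out-of-fold
    predictions.
    """
    classes, counts = np.unique(fm.labels, return_counts=True)
    if np.any(counts < folds):
        lacking = classes[counts < folds]
        raise ValueError(
            f"every class needs >= {folds} rows for {folds}-fold CV; "
            f"deficient: {list(lacking)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    y_true_all, y_pred_all = [], []
    scores_all, idx_all = [], []
    for train, val in skf.split(fm.X, fm.labels):
        clf = MedianGaussianSVC().fit(fm.X[train], fm.labels[train])
        pred = clf.predict(fm.X[val])
        fold_acc.append(float(np.mean(pred == fm.labels[val])))
        y_true_all.append(fm.labels[val])
        y_pred_all.append(pred)
        scores_all.append(clf.decision_function(fm.X[val]))
        idx_all.append(val)
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    scores = np.concatenate(scores_all)
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    roc: dict = {}
    if classes.size == 2 and scores.ndim == 1:
        fpr, tpr, _ = roc_curve(y_true == classes[1], scores)
        roc[classes[1]] = (fpr, tpr)
    elif scores.ndim == 2:
        for k, c in enumerate(classes):
            fpr, tpr, _ = roc_curve(y_true == c, scores[:, k])
            roc[c] = (fpr, tpr)
    return CVReport(accuracy=float(np.mean(fold_acc)),
                    fold_accuracies=np.array(fold_acc),
                    confusion=conf, classes=classes, roc=roc)


def rehab_trend(sessions: list[FeatureMatrix], reference: FeatureMatrix,
                folds: int = 10, seed: int = 0) -> np.ndarray:
    """Per-session patient-vs-healthy discriminability.

    Each treatment session is scored by the binary cross-validated accuracy
    of the median-Gaussian SVM separating that session's cycles (labeled
    ``patient``) from the fixed healthy reference; a decaying sequence
    indicates the patient's gait approaching the reference.
    """
    accs = []
    ref = reference.relabeled("healthy")
    for s in sessions:
        fm = FeatureMatrix.concat([s.relabeled("patient"), ref])
        accs.append(crossval_svm(fm, folds=folds, seed=seed).accuracy)
    return np.array(accs)
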