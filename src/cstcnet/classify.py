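"""F-score feature ranking and linear-SVM classification.

The two patient groups are discriminated from flattened connectivity
features (400 static, 400 dynamic, or 800 combined) under stratified
10-fold cross-validation.  Feature standardization, F-score ranking and
the choice of how many top-ranked features to keep are all performed
inside each training fold only, so no information from a held-out test
fold ever influences selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .network import ConnectivityMatrix

POSITIVE_CLASS = +1  # GE coded +1, FE coded -1; sensitivity is the GE recall

DEFAULT_K_GRID = (10, 25, 50, 100, 200, None)  # None = all features


@dataclass
class FeatureTable:
    """Subjects x features matrix with named columns and +/-1 labels."""

    x: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    feature_set: str  # static | dynamic | combined
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.x.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("feature matrix shape does not match names/labels")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +/-1")
        expected = {"static": 400, "dynamic": 400, "combined": 800}
        if self.feature_set in expected and self.x.shape[1] != expected[self.feature_set]:
            raise ValueError(
                f"{self.feature_set} feature set must have {expected[self.feature_set]} columns"
            )

    @property
    def n_features(self) -> int:
        return self.x.shape[1]


def build_feature_table(
    static: list[ConnectivityMatrix] | None,
    dynamic: list[ConnectivityMatrix] | None,
    labels,
    subject_ids=(),
) -> FeatureTable:
    """Flatten per-subject matrices row-major (full 20x20, symmetric
    duplicates and zero diagonal included) into the classifier view."""
    blocks, names, kind = [], [], []
    for tag, mats in (("static", static), ("dynamic", dynamic)):
        if mats is None:
            continue
        blocks.append(np.stack([m.flatten_features() for m in mats]))
        roi = mats[0].labels
        names += [f"{tag}:{roi[i]}~{roi[j]}" for i in range(len(roi)) for j in range(len(roi))]
        kind.append(tag)
    if not blocks:
        raise ValueError("at least one of static/dynamic must be given")
    x = np.concatenate(blocks, axis=1)
    feature_set = "combined" if len(kind) == 2 else kind[0]
    return FeatureTable(x, np.asarray(labels), tuple(names), feature_set, tuple(subject_ids))


def fisher_score(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Univariate F-score of each feature.

    F = [(m+ - m)^2 + (m- - m)^2] / [s+^2 + s-^2] with s^2 the
    unbiased within-class scatter terms; larger is more discriminative.
    Features with zero within-class scatter in both classes score 0.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    pos, neg = x[y == 1], x[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects per class")
    m, mp, mn = x.mean(0), pos.mean(0), neg.mean(0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(0, ddof=1) + neg.var(0, ddof=1)
    zero = den == 0
    # globally constant features (e.g. the zero diagonal of a flattened
    # matrix) are silently scored 0; only data-dependent degeneracy warns
    degenerate = zero & (x.var(0) > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} features with zero within-class scatter score 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(zero, 0.0, num / den)
    return f


def classification_metrics(
    truth: np.ndarray, predicted: np.ndarray, decision_values: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, AUC); class +1 is positive."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    decision_values = np.asarray(decision_values, dtype=float)
    if not (len(truth) == len(predicted) == len(decision_values)):
        raise ValueError("inputs must have equal length")
    if len(set(truth.tolist())) < 2:
        raise ValueError("both classes must be present in truth")
    tp = int(((truth == 1) & (predicted == 1)).sum())
    fn = int(((truth == 1) & (predicted == -1)).sum())
    tn = int(((truth == -1) & (predicted == -1)).sum())
    fp = int(((truth == -1) & (predicted == 1)).sum())
    accuracy = (tp + tn) / len(truth)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    auc = float(roc_auc_score((truth == 1).astype(int), decision_values))
    return accuracy, sensitivity, specificity, auc


def importance_from_weights(w: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature importance: w_j * sum_i y_i x_ij.

    The literal weight-times-label-times-data sum; the sign of w_j is
    kept (not replaced by |w_j|)."""
    return np.asarray(w, float) * (np.asarray(y, float) @ np.asarray(x, float))


@dataclass
class ClassificationResult:
    feature_set: str
    fold_accuracy: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    selected_features: list[list[str]]
    chosen_k: list[int]
    importance: np.ndarray
    feature_names: tuple[str, ...]
    true_labels: np.ndarray
    predictions: np.ndarray
    decision_values: np.ndarray
    notes: str = "positive class = GE (+1)"

    def importance_ranking(self) -> pd.DataFrame:
        order = np.argsort(-np.abs(self.importance))
        return pd.DataFrame(
            {
                "feature": np.asarray(self.feature_names)[order],
                "importance": self.importance[order],
            }
        )


def _inner_choose_k(
    x: np.ndarray, y: np.ndarray, k_grid: list[int], c: float, seed: int
) -> int:
    """Pick the retained-feature count by inner 5-fold accuracy on the
    training data only; ties go to the smaller k."""
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    n_splits = min(5, n_pos, n_neg)
    # inner folds need >= 2 per class in their own training parts
    if n_splits < 2 or min(n_pos, n_neg) < 4:
        return k_grid[0]
    inner = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best_k, best_acc = k_grid[0], -1.0
    for k in k_grid:
        accs = []
        for tr, te in inner.split(x, y):
            mu, sd = x[tr].mean(0), x[tr].std(0)
            sd = np.where(sd == 0, 1.0, sd)
            xtr, xte = (x[tr] - mu) / sd, (x[te] - mu) / sd
            order = np.argsort(-fisher_score(xtr, y[tr]), kind="stable")[:k]
            clf = SVC(kernel="linear", C=c)
            clf.fit(xtr[:, order], y[tr])
            accs.append(float((clf.predict(xte[:, order]) == y[te]).mean()))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_k = acc, k
    return best_k


def crossvalidated_svm(
    table: FeatureTable,
    n_folds: int = 10,
    seed: int = 0,
    k_grid=DEFAULT_K_GRID,
    c: float = 1.0,
) -> ClassificationResult:
    """Stratified k-fold linear-SVM classification with strictly
    fold-internal standardization and F-score feature selection."""
    x, y = table.x, table.labels.astype(int)
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects per class")
    grid = sorted({table.n_features if k is None else int(k) for k in k_grid})
    if any(k > table.n_features for k in grid):
        warnings.warn("k_grid entries exceeding the feature count were clipped")
        grid = sorted({min(k, table.n_features) for k in grid})

    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc, fold_sens, fold_spec = [], [], []
    selected, chosen_k = [], []
    importance_folds = []
    all_truth, all_pred, all_dec = [], [], []
    for fold, (tr, te) in enumerate(outer.split(x, y)):
        mu, sd = x[tr].mean(0), x[tr].std(0)
        sd = np.where(sd == 0, 1.0, sd)
        xtr, xte = (x[tr] - mu) / sd, (x[te] - mu) / sd
        k = _inner_choose_k(xtr, y[tr], grid, c, seed + 1)
        order = np.argsort(-fisher_score(xtr, y[tr]), kind="stable")[:k]
        clf = SVC(kernel="linear", C=c)
        clf.fit(xtr[:, order], y[tr])
        pred = clf.predict(xte[:, order])
        dec = clf.decision_function(xte[:, order])
        if clf.classes_[1] != 1:  # decision sign follows class order
            dec = -dec
        tp = ((y[te] == 1) & (pred == 1)).sum()
        fn = ((y[te] == 1) & (pred == -1)).sum()
        tn = ((y[te] == -1) & (pred == -1)).sum()
        fp = ((y[te] == -1) & (pred == 1)).sum()
        fold_acc.append(float((pred == y[te]).mean()))
        fold_sens.append(float(tp / (tp + fn)) if tp + fn else np.nan)
        fold_spec.append(float(tn / (tn + fp)) if tn + fp else np.nan)
        selected.append([table.feature_names[j] for j in order])
        chosen_k.append(int(k))
        w_full = np.zeros(table.n_features)
        w_full[order] = clf.coef_.ravel()
        imp = np.zeros(table.n_features)
        imp[order] = importance_from_weights(clf.coef_.ravel(), xtr[:, order], y[tr])
        importance_folds.append(imp)
        all_truth.append(y[te])
        all_pred.append(pred)
        all_dec.append(dec)

    truth = np.concatenate(all_truth)
    pred = np.concatenate(all_pred)
    dec = np.concatenate(all_dec)
    accuracy, sensitivity, specificity, auc = classification_metrics(truth, pred, dec)
    return ClassificationResult(
        feature_set=table.feature_set,
        fold_accuracy=fold_acc,
        fold_sensitivity=fold_sens,
        fold_specificity=fold_spec,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        selected_features=selected,
        chosen_k=chosen_k,
        importance=np.mean(importance_folds, axis=0),
        feature_names=table.feature_names,
        true_labels=truth,
        predictions=pred,
        decision_values=dec,
    )


def feature_importance(result: ClassificationResult, table: FeatureTable) -> pd.DataFrame:
    """Ranked fold-averaged importance with edge names."""
    if result.feature_names != table.feature_names:
        raise ValueError("result and table feature names differ")
    return result.importance_ranking()
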