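"""Classification metrics and cross-validated objective evaluation.

Sn = TP/(TP+FN) and Sp = TN/(TN+FP) control false negatives and false
positives respectively; MCC balances them and ACA = (Sn+Sp)/2 is the
average class-wise accuracy.  Cross-validated objectives pool confusion
counts over stratified folds before computing the triple (micro
aggregation), which is robust when folds contain few negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import classifier as _clf


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts for +-1 labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def sn_sp_mcc_aca(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, MCC, ACA); errors if either class is absent."""
    if c.TP + c.FN < 1:
        raise ValueError("Sn undefined: no positive examples (TP+FN=0)")
    if c.TN + c.FP < 1:
        raise ValueError("Sp undefined: no negative examples (TN+FP=0)")
    sn = c.TP / (c.TP + c.FN)
    sp = c.TN / (c.TN + c.FP)
    return sn, sp, mcc(c), (sn + sp) / 2


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """(precision, recall); precision is undefined when TP+FP=0."""
    if c.TP + c.FP < 1:
        raise ValueError("precision undefined: no predicted positives (TP+FP=0)")
    if c.TP + c.FN < 1:
        raise ValueError("recall undefined: no positive examples (TP+FN=0)")
    return c.TP / (c.TP + c.FP), c.TP / (c.TP + c.FN)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks -> half credit for ties
    pos_rank_sum = float(np.sum(ranks[labels == 1]))
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def cv_confusion(
    X: np.ndarray,
    y: np.ndarray,
    mask: Iterable[int] | None,
    params: "_clf.SVMParams | None" = None,
    k: int = 5,
    seed: int = 0,
) -> ConfusionCounts:
    """Confusion counts pooled over stratified k-fold CV predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    for cls in (1, -1):
        if int(np.sum(y == cls)) < k:
            raise ValueError(f"class {cls:+d} has fewer than k={k} examples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for tr, te in skf.split(X, y):
        model = _clf.train(X[tr], y[tr], mask, params)
        c = confusion(y[te], model.predict(X[te]))
        tp += c.TP
        tn += c.TN
        fp += c.FP
        fn += c.FN
    return ConfusionCounts(tp, tn, fp, fn)


def cv_objectives(
    X: np.ndarray,
    y: np.ndarray,
    mask: Iterable[int] | None,
    params: "_clf.SVMParams | None" = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(Sn, Sp, MCC) from pooled stratified k-fold CV counts."""
    sn, sp, m, _ = sn_sp_mcc_aca(cv_confusion(X, y, mask, params, k, seed))
    return sn, sp, m


def category_correlation(
    pos_matrix: np.ndarray,
    neg_matrix: np.ndarray,
    category: int,
    catalog=None,
) -> float:
    """Pearson r between class mean vectors of one category's features.

    The per-feature means over positive and over negative examples are
    correlated; a high r suggests the category discriminates poorly.
    """
    from .featurize import build_catalog

    catalog = catalog or build_catalog()
    idx = np.array(catalog.category_indices(category)) - 1
    if len(idx) < 2:
        raise ValueError(f"category {category} has fewer than 2 features")
    pos_matrix = np.asarray(pos_matrix, dtype=float)
    neg_matrix = np.asarray(neg_matrix, dtype=float)
    if pos_matrix.size == 0 or neg_matrix.size == 0:
        raise ValueError("both class matrices must be non-empty")
    pos_mean = pos_matrix[:, idx].mean(axis=0)
    neg_mean = neg_matrix[:, idx].mean(axis=0)
    r, _ = stats.pearsonr(pos_mean, neg_mean)
    return float(r)
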