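"""RBF-kernel SVM training, decision-value scoring and grid selection.

The decision value f(x) = sum_i alpha_i y_i K(x_i, x) + b with the RBF
kernel K(u, v) = exp(-gamma ||u - v||^2) is the prediction score; the
predicted class is its sign (a value of exactly 0 goes to the negative
class).  Features are min-max scaled to [0, 1] on the training data before
fitting; the scaler is stored in the model so scoring applies mask ->
scaler -> hyperplane in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .featurize import N_FEATURES, CATALOG_VERSION

#: libsvm fit tolerance, fixed for reproducibility
FIT_TOL = 1e-3

#: package defaults where no tuned values are available
DEFAULT_C = 1.0
DEFAULT_GAMMA = 0.1


@dataclass(frozen=True)
class SVMParams:
    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be strictly positive")


def default_grid() -> list[SVMParams]:
    """The classic exponential (C, gamma) grid."""
    return [
        SVMParams(C=2.0**c, gamma=2.0**g)
        for c in range(-5, 16, 2)
        for g in range(-15, 4, 2)
    ]


def _mask_columns(X: np.ndarray, mask: Iterable[int]) -> np.ndarray:
    idx = sorted(set(int(i) for i in mask))
    if not idx:
        raise ValueError("empty feature mask")
    if idx[0] < 1 or idx[-1] > X.shape[1]:
        raise ValueError("mask index out of range for the given matrix")
    return X[:, np.array(idx) - 1]


@dataclass
class TrainedModel:
    """A fitted scaler + RBF-SVM + feature mask, serializable with joblib."""

    params: SVMParams
    feature_mask: tuple[int, ...]
    scaler: MinMaxScaler
    svc: SVC
    catalog_version: str = CATALOG_VERSION

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == len(self.feature_mask):
            pass  # already masked
        elif X.shape[1] >= max(self.feature_mask):
            X = _mask_columns(X, self.feature_mask)
        else:
            raise ValueError(
                f"expected {len(self.feature_mask)} (masked) or full-width "
                f"vectors, got width {X.shape[1]}"
            )
        return self.scaler.transform(X)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._prepare(X))

    def score(self, x: np.ndarray) -> float:
        """Decision value of a single feature vector."""
        return float(self.decision_values(np.atleast_2d(x))[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 iff the decision value is > 0, else -1."""
        return np.where(self.decision_values(X) > 0, 1, -1)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise ValueError(f"{path} does not contain a TrainedModel")
        return model


def train(
    X: np.ndarray,
    y: np.ndarray,
    mask: Iterable[int] | None = None,
    params: SVMParams | None = None,
) -> TrainedModel:
    """Fit the scaler and RBF-SVM on the masked columns of ``X``.

    ``mask`` uses 1-based catalog indices; ``None`` means all columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    params = params or SVMParams()
    mask = tuple(sorted(set(mask))) if mask is not None else tuple(range(1, X.shape[1] + 1))
    classes = set(np.unique(y))
    if classes != {-1, 1}:
        raise ValueError(f"labels must contain both classes {{+1,-1}}, got {sorted(classes)}")
    Xm = _mask_columns(X, mask)
    scaler = MinMaxScaler().fit(Xm)
    svc = SVC(
        kernel="rbf",
        C=params.C,
        gamma=params.gamma,
        tol=FIT_TOL,
        shrinking=True,
        cache_size=100,
    )
    svc.fit(scaler.transform(Xm), y)
    return TrainedModel(params=params, feature_mask=mask, scaler=scaler, svc=svc)


def grid_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    mask: Iterable[int] | None = None,
    grid: Sequence[SVMParams] | None = None,
) -> SVMParams:
    """(C, gamma) maximizing accuracy on a held-out validation set.

    Ties break to the smallest C, then the smallest gamma.
    """
    grid = list(default_grid() if grid is None else grid)
    if not grid:
        raise ValueError("empty parameter grid")
    best: tuple[float, float, float] | None = None
    best_params: SVMParams | None = None
    for p in grid:
        model = train(X_train, y_train, mask, p)
        acc = float(np.mean(model.predict(X_val) == np.asarray(y_val)))
        key = (-acc, p.C, p.gamma)
        if best is None or key < best:
            best = key
            best_params = p
    return best_params
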