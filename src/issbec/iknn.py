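"""Improved K-nearest-neighbour base learner (IKNN).

The learner replaces plain Euclidean KNN with a weighted Minkowski
distance,

    WM(a, b) = [ sum_i W_i |a_i - b_i|^rho ]^(1/rho),   rho >= 1,

where the per-feature weights come from a leave-one-feature-out accuracy
probe: acc_e is the cross-validated accuracy of a conventional KNN
(averaged over k in {3, 5, 7}) on all features, acc_0(i) the same with
feature i removed, and the "value parameter" nu_i = 1 - (acc_0(i) - acc_e)
down-weights features whose removal helps.  Weights are the normalized
value parameters (they sum to 1).  Prediction takes the k nearest training
points under the weighted distance and holds a plurality vote (default);
an average-distance variant instead averages each class's distances among
the k neighbours and picks the smallest average (ties: larger neighbour
count, then lower class index).

The leave-one-feature-out probe precomputes per-feature squared-difference
contributions so each of the t accuracy evaluations reuses one pooled
distance matrix instead of refitting a KNN from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass
class IKNNConfig:
    k: int = 5
    minkowski_order: float = 2.0
    k_values: tuple[int, ...] = (3, 5, 7)
    cv_folds: int = 3
    decision_rule: str = "majority"   # or "average_distance"
    scope: str = "neighbors"   # or "all": average over every training point
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minkowski_order < 1:
            raise ValueError("minkowski_order must be >= 1")
        if self.scope not in ("neighbors", "all"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.decision_rule not in ("majority", "average_distance"):
            raise ValueError(f"unknown decision_rule {self.decision_rule!r}")


@dataclass
class IKNNModel:
    train_matrix: np.ndarray
    train_labels: np.ndarray
    classes: np.ndarray
    feature_weights: np.ndarray
    value_params: np.ndarray
    baseline_accuracy: float
    ablation_accuracies: np.ndarray
    config: IKNNConfig


def wminkowski_distance(a: np.ndarray, b: np.ndarray, W: np.ndarray,
                        rho: float = 2.0) -> float:
    """Weighted Minkowski distance between two vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    W = np.asarray(W, float)
    if rho < 1:
        raise ValueError("rho must be >= 1")
    if a.shape != b.shape or a.shape != W.shape:
        raise ValueError("length mismatch")
    return float(np.sum(W * np.abs(a - b) ** rho) ** (1.0 / rho))


def _pairwise_wmink(Q: np.ndarray, X: np.ndarray, W: np.ndarray,
                    rho: float) -> np.ndarray:
    diff = np.abs(Q[:, None, :] - X[None, :, :]) ** rho
    return np.sum(diff * W, axis=2) ** (1.0 / rho)


def _majority_vote(neigh_labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Plurality vote per row; ties to the lowest class index."""
    n, _ = neigh_labels.shape
    counts = np.stack([(neigh_labels == c).sum(axis=1) for c in classes], axis=1)
    return classes[np.argmax(counts, axis=1)]


def _cv_accuracy_from_d2(D2: np.ndarray, y: np.ndarray, classes: np.ndarray,
                         k_values, folds: int, seed: int) -> float:
    """Mean CV accuracy of majority-vote KNN given squared distances."""
    n = len(y)
    _, counts = np.unique(y, return_counts=True)
    eff_folds = min(folds, counts.min())
    if eff_folds < folds:
        warnings.warn(
            f"smallest class has {counts.min()} samples; using {eff_folds} folds",
            RuntimeWarning,
        )
    if eff_folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        sub = D2[np.ix_(test_idx, train_idx)]
        order = np.argsort(sub, axis=1, kind="stable")
        for k in k_values:
            kk = min(k, len(train_idx))
            neigh = y[train_idx[order[:, :kk]]]
            pred = _majority_vote(neigh, classes)
            accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))


def knn_cv_accuracy(X: np.ndarray, y: np.ndarray,
                    k_values=(3, 5, 7), folds: int = 3,
                    seed: int = 0) -> float:
    """Stratified-CV accuracy of conventional Euclidean KNN, averaged over k."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    sq = np.sum(X * X, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    return _cv_accuracy_from_d2(D2, y, classes, k_values, folds, seed)


def compute_value_params(X: np.ndarray, y: np.ndarray,
                         k_values=(3, 5, 7), folds: int = 3, seed: int = 0):
    """Leave-one-feature-out value parameters (nu, acc_e, acc_0 vector)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    t = X.shape[1]
    if t < 2:
        raise ValueError("need at least 2 features")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    # per-feature squared-difference contributions; full matrix is their sum
    contrib = (X[:, None, :] - X[None, :, :]) ** 2
    D2_full = contrib.sum(axis=2)
    acc_e = _cv_accuracy_from_d2(D2_full, y, classes, k_values, folds, seed)
    acc_0 = np.empty(t)
    for i in range(t):
        acc_0[i] = _cv_accuracy_from_d2(D2_full - contrib[:, :, i], y, classes,
                                        k_values, folds, seed)
    nu = np.maximum(1.0 - (acc_0 - acc_e), 1e-6)
    return nu, acc_e, acc_0


def compute_weights(value_params: np.ndarray) -> np.ndarray:
    """Normalize the value parameters so the weights sum to 1."""
    nu = np.asarray(value_params, float)
    if np.any(nu <= 0):
        raise ValueError("value parameters must be positive (clamp upstream)")
    return nu / nu.sum()


def fit_iknn(X: np.ndarray, y: np.ndarray,
             config: IKNNConfig | None = None) -> IKNNModel:
    config = config or IKNNConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    nu, acc_e, acc_0 = compute_value_params(
        X, y, config.k_values, config.cv_folds, config.seed
    )
    return IKNNModel(
        train_matrix=X, train_labels=y, classes=np.unique(y),
        feature_weights=compute_weights(nu), value_params=nu,
        baseline_accuracy=acc_e, ablation_accuracies=acc_0, config=config,
    )


def _class_scores(D: np.ndarray, labels: np.ndarray, classes: np.ndarray,
                  k: int, scope: str):
    """Per-query (avg distance, neighbour count) per class; inf where absent."""
    nq, nt = D.shape
    avg = np.full((nq, classes.size), np.inf)
    cnt = np.zeros((nq, classes.size), dtype=int)
    if scope == "all":
        for j, c in enumerate(classes):
            cols = labels == c
            avg[:, j] = D[:, cols].mean(axis=1)
            cnt[:, j] = cols.sum()
        return avg, cnt
    kk = min(k, nt)
    order = np.argsort(D, axis=1, kind="stable")[:, :kk]
    for q in range(nq):
        neigh = order[q]
        for j, c in enumerate(classes):
            sel = neigh[labels[neigh] == c]
            if sel.size:
                avg[q, j] = D[q, sel].mean()
                cnt[q, j] = sel.size
    return avg, cnt


def predict_iknn(model: IKNNModel, Q: np.ndarray) -> np.ndarray:
    """Classify queries by weighted-Minkowski k-nearest neighbours."""
    Q = np.atleast_2d(np.asarray(Q, float))
    cfg = model.config
    k = cfg.k
    if k > len(model.train_labels):
        warnings.warn("k exceeds training size; clamping", RuntimeWarning)
        k = len(model.train_labels)
    D = _pairwise_wmink(Q, model.train_matrix, model.feature_weights,
                        cfg.minkowski_order)
    if cfg.decision_rule == "majority":
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        return _majority_vote(model.train_labels[order], model.classes)
    avg, cnt = _class_scores(D, model.train_labels, model.classes, k, cfg.scope)
    # smallest average distance; ties -> larger count, then lower class index
    out = np.empty(Q.shape[0], dtype=model.classes.dtype)
    for q in range(Q.shape[0]):
        best = np.lexsort((np.arange(model.classes.size), -cnt[q], avg[q]))[0]
        out[q] = model.classes[best]
    return out


def iknn_decision_scores(model: IKNNModel, Q: np.ndarray) -> np.ndarray:
    """Per-class scores (negative average distance; higher is better)."""
    Q = np.atleast_2d(np.asarray(Q, float))
    cfg = model.config
    k = min(cfg.k, len(model.train_labels))
    D = _pairwise_wmink(Q, model.train_matrix, model.feature_weights,
                        cfg.minkowski_order)
    avg, _ = _class_scores(D, model.train_labels, model.classes, k, cfg.scope)
    finite = np.where(np.isfinite(avg), avg, np.nan)
    worst = np.nanmax(finite) if np.isfinite(finite).any() else 1.0
    return -np.where(np.isfinite(avg), avg, worst * 10.0)
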