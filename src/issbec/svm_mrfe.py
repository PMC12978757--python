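"""Hybrid margin/separability feature selection (SVM-MRFE) and fusion.

Each data partition is reduced independently by backward elimination: a
linear maximum-margin classifier is refit on the surviving features at
every iteration, features are scored by a convex combination of the
squared SVM weights and a modified Fisher separability score (both
max-normalized),

    R(f) = alpha * w_f^2 / max w^2 + (1 - alpha) * Ms(f) / max Ms,

and the lowest-ranked fraction is dropped until the target size is
reached.  The per-partition selections are then fused by a deduplicated
union over original feature indices, with provenance recording which
partitions selected each feature.

The modified Fisher score studentizes the global feature mean against the
grand mean of the partition matrix and scales by the standard error of the
feature mean; the classical Fisher score is kept alongside (and is the
conventional-RFE ablation path at alpha = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC


@dataclass
class FisherScores:
    s: np.ndarray
    ms: np.ndarray
    class_means: np.ndarray        # V x d
    class_sizes: np.ndarray        # V
    class_sds: np.ndarray          # V x d
    global_means: np.ndarray
    global_sds: np.ndarray
    standard_errors: np.ndarray
    studentized_means: np.ndarray
    grand_mean: float
    n_classes: int


@dataclass
class RankingResult:
    svm_weights_sq: np.ndarray
    ms_scores: np.ndarray
    hybrid_rank: np.ndarray
    alpha_rank: float


@dataclass
class SelectedFeatures:
    partition_id: int
    kept_indices: list[int]
    elimination_trace: list[tuple[int, list[int]]] = field(default_factory=list)


@dataclass
class FusedFeatures:
    indices: list[int]
    provenance: dict[int, set[int]]


@dataclass
class MRFEConfig:
    alpha_rank: float = 0.5
    n_select: int = 50
    drop_fraction: float = 0.10
    svm_regularization: float = 1.0
    ms_variant: str = "literal"    # or "classic-denominator"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_rank <= 1.0:
            raise ValueError("alpha_rank must lie in [0, 1]")
        if self.n_select < 2:
            raise ValueError("n_select must be >= 2")
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must lie in (0, 1)")
        if self.ms_variant not in ("literal", "classic-denominator"):
            raise ValueError(f"unknown ms_variant {self.ms_variant!r}")


def _class_stats(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    sizes = np.array([(y == c).sum() for c in classes])
    if np.any(sizes < 2):
        raise ValueError("need at least 2 samples per class")
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    sds = np.stack([X[y == c].std(axis=0, ddof=1) for c in classes])
    return classes, sizes, means, sds


def _fisher_full(X: np.ndarray, y: np.ndarray,
                 ms_variant: str = "literal") -> FisherScores:
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape
    classes, sizes, cmeans, csds = _class_stats(X, y)

    gmean = X.mean(axis=0)
    gsd = X.std(axis=0, ddof=1)
    if n < 3:
        raise ValueError("need n >= 3 for the standard error of the mean")
    se = gsd / math.sqrt(n)
    grand = float(X.mean())

    # classical: s = sum_d n_d (mu_dc - mu)^2 / sum_d n_d sd_dc^2
    num_s = np.sum(sizes[:, None] * (cmeans - gmean) ** 2, axis=0)
    den_s = np.sum(sizes[:, None] * csds ** 2, axis=0)
    s = np.where(den_s > 0, num_s / np.where(den_s > 0, den_s, 1.0), 0.0)

    # modified: studentized global mean, SE-scaled denominator
    phi = np.where(se > 0, (gmean - grand) / np.where(se > 0, se, 1.0), 0.0)
    num_m = np.sum(sizes[:, None] * (cmeans - phi) ** 2, axis=0)
    if ms_variant == "literal":
        den_m = sizes.sum() * se
    else:
        den_m = den_s
    ms = np.where((den_m > 0) & (se > 0),
                  num_m / np.where(den_m > 0, den_m, 1.0), 0.0)

    return FisherScores(
        s=s, ms=ms, class_means=cmeans, class_sizes=sizes, class_sds=csds,
        global_means=gmean, global_sds=gsd, standard_errors=se,
        studentized_means=phi, grand_mean=grand, n_classes=classes.size,
    )


def fisher_score(X: np.ndarray, y: np.ndarray) -> FisherScores:
    """Classical Fisher separability score per feature (``s`` field)."""
    return _fisher_full(X, y)


def modified_fisher_score(X: np.ndarray, y: np.ndarray,
                          ms_variant: str = "literal") -> FisherScores:
    """Modified Fisher score per feature (``ms`` field).

    Constant features (zero standard error) score 0 by convention.
    """
    return _fisher_full(X, y, ms_variant=ms_variant)


def hybrid_rank(svm_weights_sq: np.ndarray, ms: np.ndarray,
                alpha_rank: float = 0.5) -> np.ndarray:
    """Convex combination of max-normalized squared weights and Ms scores."""
    w2 = np.asarray(svm_weights_sq, float)
    m = np.asarray(ms, float)
    if w2.shape != m.shape:
        raise ValueError("length mismatch")
    wterm = w2 / w2.max() if w2.max() > 0 else np.zeros_like(w2)
    mterm = m / m.max() if m.max() > 0 else np.zeros_like(m)
    return alpha_rank * wterm + (1.0 - alpha_rank) * mterm


def _svm_weights_sq(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> np.ndarray:
    """Per-feature squared weights of a linear max-margin fit.

    For >2 classes the squared weights of the one-vs-rest binary problems
    are summed per feature.
    """
    classes = np.unique(y)
    if classes.size == 2:
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(X, y)
        return np.asarray(clf.coef_).ravel() ** 2
    clf = OneVsRestClassifier(SVC(kernel="linear", C=C, random_state=seed))
    clf.fit(X, y)
    coefs = np.vstack([est.coef_ for est in clf.estimators_])
    return np.sum(coefs ** 2, axis=0)


def rank_features(X: np.ndarray, y: np.ndarray,
                  config: MRFEConfig) -> RankingResult:
    """One ranking pass: linear SVM weights + modified Fisher, combined."""
    w2 = _svm_weights_sq(X, y, config.svm_regularization, config.seed)
    ms = modified_fisher_score(X, y, config.ms_variant).ms
    return RankingResult(
        svm_weights_sq=w2, ms_scores=ms,
        hybrid_rank=hybrid_rank(w2, ms, config.alpha_rank),
        alpha_rank=config.alpha_rank,
    )


def mrfe_select(X: np.ndarray, y: np.ndarray, config: MRFEConfig,
                partition_id: int = 0) -> SelectedFeatures:
    """Backward elimination down to ``n_select`` features.

    Refits the ranking classifier on the surviving columns every iteration
    and drops the lowest-ranked ceil(drop_fraction * remaining) features
    (never crossing n_select).  Rank ties are broken by dropping the higher
    original index first.  Indices in the result refer to the ORIGINAL
    column positions of X.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    d = X.shape[1]
    remaining = np.arange(d)
    trace: list[tuple[int, list[int]]] = []
    iteration = 0
    while remaining.size > config.n_select:
        try:
            ranks = rank_features(X[:, remaining], y, config).hybrid_rank
        except ValueError as exc:
            raise ValueError(
                f"partition {partition_id}: ranking classifier fit failed ({exc})"
            ) from exc
        n_drop = math.ceil(config.drop_fraction * remaining.size)
        n_drop = min(n_drop, remaining.size - config.n_select)
        n_drop = max(n_drop, 1)
        # ascending rank; ties -> higher original index first
        order = np.lexsort((-remaining, ranks))
        drop_local = order[:n_drop]
        dropped = sorted(int(remaining[i]) for i in drop_local)
        trace.append((iteration, dropped))
        keep_mask = np.ones(remaining.size, dtype=bool)
        keep_mask[drop_local] = False
        remaining = remaining[keep_mask]
        iteration += 1
    return SelectedFeatures(
        partition_id=partition_id,
        kept_indices=sorted(int(i) for i in remaining),
        elimination_trace=trace,
    )


def fuse_features(per_partition: list[SelectedFeatures]) -> FusedFeatures:
    """Deduplicated sorted union of the partitions' selections."""
    if not per_partition:
        raise ValueError("no partition selections to fuse")
    provenance: dict[int, set[int]] = {}
    for sel in per_partition:
        for idx in sel.kept_indices:
            provenance.setdefault(int(idx), set()).add(sel.partition_id)
    if not provenance:
        raise ValueError("fused feature set is empty")
    return FusedFeatures(indices=sorted(provenance), provenance=provenance)
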