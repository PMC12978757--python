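"""Subspace-rotation ensemble classifier (ISSBEC).

Each ensemble block draws a weighted random feature subspace from the
fused feature set, builds a rotation-forest-style orthogonal rotation
(random disjoint feature groups, PCA fitted per group on a 75% row
subsample, block-diagonal assembly rearranged to the original column
order), blends the subspace with its rotated image,

    H = alpha * S + (1 - alpha) * S @ R,

and fits one heterogeneous base learner (random forest, RBF SVM or the
improved KNN, cycling in that order).  Predictions are fused by plurality
vote; per-class vote fractions double as scores for ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .iknn import IKNNConfig, fit_iknn, iknn_decision_scores, predict_iknn
from .svm_mrfe import FusedFeatures


@dataclass
class SubspaceSpec:
    block_id: int
    primary_indices: np.ndarray
    secondary_indices: np.ndarray
    weight_vector: np.ndarray
    overlap_coeff: float
    column_multipliers: np.ndarray


@dataclass
class RotationModel:
    n_features: int
    groups: list[np.ndarray]
    group_size_draw: int
    loadings: list[np.ndarray]
    rotation: np.ndarray


@dataclass
class EnsembleConfig:
    n_blocks: int = 3
    learner_kinds: tuple[str, ...] = ("random_forest", "svm", "iknn")
    subspace_ratio: float = 0.5     # gamma
    overlap_coeff: float = 0.3      # lambda
    alpha_mse: float = 0.5
    bootstrap_fraction: float = 0.75
    bootstrap_replace: bool = False
    group_size_choices: tuple[int, ...] = (2, 3, 4)
    mse_rotation: str = "grouped_pca"  # or "random": QR of a Gaussian draw
    unit_weights: bool = False         # force W_i = 1 (diagnostic baseline)
    rf_n_estimators: int = 100
    svm_regularization: float = 1.0
    iknn: IKNNConfig = field(default_factory=IKNNConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subspace_ratio <= 1.0:
            raise ValueError("subspace_ratio must lie in (0, 1]")
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must lie in (0, 1]")
        if not 0.0 <= self.alpha_mse <= 1.0:
            raise ValueError("alpha_mse must lie in [0, 1]")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.mse_rotation not in ("grouped_pca", "random"):
            raise ValueError(f"unknown mse_rotation {self.mse_rotation!r}")


class _Learner:
    """Uniform fit/predict/scores facade over the heterogeneous learners."""

    def __init__(self, kind: str, config: EnsembleConfig, seed: int):
        self.kind = kind
        self.config = config
        self.seed = seed
        self._fitted = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Learner":
        if self.kind == "random_forest":
            clf = RandomForestClassifier(
                n_estimators=self.config.rf_n_estimators,
                random_state=self.seed, n_jobs=1,
            )
            clf.fit(X, y)
            self._fitted = clf
            self.classes_ = clf.classes_
        elif self.kind == "svm":
            clf = SVC(kernel="rbf", C=self.config.svm_regularization,
                      random_state=self.seed)
            clf.fit(X, y)
            self._fitted = clf
            self.classes_ = clf.classes_
        elif self.kind == "iknn":
            from dataclasses import replace
            model = fit_iknn(X, y, replace(self.config.iknn, seed=self.seed))
            self._fitted = model
            self.classes_ = model.classes
        else:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._fitted is None:
            raise RuntimeError("learner not fitted")
        if self.kind == "iknn":
            return predict_iknn(self._fitted, X)
        return self._fitted.predict(X)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores aligned with self.classes_ (higher = more likely)."""
        if self.kind == "random_forest":
            return self._fitted.predict_proba(X)
        if self.kind == "svm":
            df = self._fitted.decision_function(X)
            if df.ndim == 1:  # binary: one column for the positive class
                return np.column_stack([-df, df])
            return df
        return iknn_decision_scores(self._fitted, X)


@dataclass
class EnsembleModel:
    blocks: list[tuple[SubspaceSpec, RotationModel, float, _Learner]]
    classes: np.ndarray
    config: EnsembleConfig


def _n_fused(fused) -> int:
    if isinstance(fused, FusedFeatures):
        return len(fused.indices)
    return int(fused)


def draw_subspace(fused, config: EnsembleConfig, block_id: int,
                  rng_seed: int) -> SubspaceSpec:
    """Draw one weighted subspace over the fused feature positions.

    M = max(2, round(gamma * |fused|)); primary and secondary index sets are
    independent uniform draws without replacement (primary sorted); weights
    are Uniform(0.5, 1.5); columns also present in the secondary set get a
    (1 + lambda) overlap bonus on their multiplier.
    """
    n = _n_fused(fused)
    if n < 2:
        raise ValueError("need at least 2 fused features")
    M = max(2, round(config.subspace_ratio * n))
    if M > n:
        raise ValueError("subspace size exceeds the fused feature count")
    rng = np.random.default_rng(rng_seed)
    primary = np.sort(rng.choice(n, size=M, replace=False))
    secondary = np.sort(rng.choice(n, size=M, replace=False))
    weights = np.ones(M) if config.unit_weights else rng.uniform(0.5, 1.5, size=M)
    bonus = np.isin(primary, secondary)
    multipliers = weights * (1.0 + config.overlap_coeff * bonus)
    return SubspaceSpec(
        block_id=block_id, primary_indices=primary, secondary_indices=secondary,
        weight_vector=weights, overlap_coeff=config.overlap_coeff,
        column_multipliers=multipliers,
    )


def apply_subspace(X: np.ndarray, spec: SubspaceSpec) -> np.ndarray:
    """Restrict X to the primary columns, scaled by the multipliers."""
    X = np.asarray(X, float)
    if spec.primary_indices.max() >= X.shape[1]:
        raise IndexError("subspace index out of range for this matrix")
    return X[:, spec.primary_indices] * spec.column_multipliers


def build_rotation(S: np.ndarray, y: np.ndarray, config: EnsembleConfig,
                   rng_seed: int) -> RotationModel:
    """Rotation-forest-style orthogonal rotation for one block.

    Columns are randomly partitioned into groups of a randomly drawn size;
    each group's full PCA loading matrix is fitted on a 75% row subsample
    (without replacement by default) and the loadings are assembled
    block-diagonally, rearranged back to the original column order.
    A zero-variance group keeps identity loadings.
    """
    S = np.asarray(S, float)
    n, M = S.shape
    if n < 4:
        raise ValueError("need at least 4 rows to build a rotation")
    rng = np.random.default_rng(rng_seed)

    if config.mse_rotation == "random":
        Q, _ = np.linalg.qr(rng.normal(size=(M, M)))
        return RotationModel(n_features=M, groups=[np.arange(M)],
                             group_size_draw=M, loadings=[Q], rotation=Q)

    g = int(rng.choice(config.group_size_choices))
    perm = rng.permutation(M)
    groups = [perm[i:i + g] for i in range(0, M, g)]
    n_sub = math.ceil(config.bootstrap_fraction * n)
    rotation = np.zeros((M, M))
    loadings = []
    for grp in groups:
        rows = rng.choice(n, size=n_sub, replace=config.bootstrap_replace)
        sub = S[np.ix_(rows, grp)]
        centered = sub - sub.mean(axis=0)
        if np.allclose(centered, 0.0):
            warnings.warn("zero-variance rotation group; identity loadings",
                          RuntimeWarning)
            V = np.eye(len(grp))
        else:
            # full orthonormal loading basis (all principal axes)
            _, _, Vt = np.linalg.svd(centered, full_matrices=True)
            V = Vt.T
        loadings.append(V)
        rotation[np.ix_(grp, grp)] = V
    return RotationModel(n_features=M, groups=groups, group_size_draw=g,
                         loadings=loadings, rotation=rotation)


def mixed_enhance(S: np.ndarray, model: RotationModel,
                  alpha_mse: float) -> np.ndarray:
    """Convex blend of the subspace with its rotated image."""
    S = np.asarray(S, float)
    if S.shape[1] != model.n_features:
        raise ValueError("column count does not match the rotation")
    return alpha_mse * S + (1.0 - alpha_mse) * (S @ model.rotation)


def block_seed_for(master_seed: int, block_id: int) -> int:
    """Per-block seed derived from the master seed (stable, < 2**31)."""
    child = np.random.SeedSequence(master_seed).spawn(block_id + 1)[block_id]
    return int(child.generate_state(1)[0] % (2**31 - 1))


def fit_ensemble(X: np.ndarray, y: np.ndarray,
                 config: EnsembleConfig) -> EnsembleModel:
    """Fit all blocks on X (already restricted to the fused features)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < 8:
        raise ValueError("need at least 8 samples")
    if classes.size == 2 and config.n_blocks % 2 == 0:
        warnings.warn("even number of blocks: binary votes can tie",
                      RuntimeWarning)
    blocks = []
    for b in range(config.n_blocks):
        block_seed = block_seed_for(config.seed, b)
        kind = config.learner_kinds[b % len(config.learner_kinds)]
        spec = draw_subspace(X.shape[1], config, b, block_seed)
        S = apply_subspace(X, spec)
        rot = build_rotation(S, y, config, block_seed + 1)
        H = mixed_enhance(S, rot, config.alpha_mse)
        try:
            learner = _Learner(kind, config, block_seed).fit(H, y)
        except Exception as exc:
            raise RuntimeError(
                f"block {b} ({kind}) failed to fit: {exc}"
            ) from exc
        blocks.append((spec, rot, config.alpha_mse, learner))
    return EnsembleModel(blocks=blocks, classes=classes, config=config)


def predict(model: EnsembleModel, X: np.ndarray):
    """Plurality vote over blocks; returns (labels, per-class vote fractions).

    Vote ties are broken by the larger summed per-class learner score,
    then by the lower class index.
    """
    X = np.asarray(X, float)
    classes = model.classes
    n = X.shape[0]
    votes = np.zeros((n, classes.size))
    score_sum = np.zeros((n, classes.size))
    for spec, rot, alpha, learner in model.blocks:
        H = mixed_enhance(apply_subspace(X, spec), rot, alpha)
        pred = learner.predict(H)
        for j, c in enumerate(classes):
            votes[:, j] += pred == c
        sc = learner.scores(H)
        # align learner class order with the ensemble's
        col = {c: i for i, c in enumerate(learner.classes_)}
        for j, c in enumerate(classes):
            if c in col:
                score_sum[:, j] += sc[:, col[c]]
    fractions = votes / len(model.blocks)
    labels = np.empty(n, dtype=classes.dtype)
    for i in range(n):
        order = np.lexsort((np.arange(classes.size), -score_sum[i], -votes[i]))
        labels[i] = classes[order[0]]
    return labels, fractions
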