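"""Synthetic expression-like matrices with known ground truth.

Two generators cover the two things the stack needs to be tested against:

``generate_classification``
    Labelled matrices in the small-n / large-d regime typical of microarray
    benchmarks (tens to ~200 samples, hundreds to ~2000 features).  A known
    subset of features is informative: the class means on those features are
    separated by ``effect_size`` noise standard deviations (with a random
    sign per feature); the rest are pure noise.  Optional latent-cluster
    structure and equicorrelation among informative features mimic the
    sample-subtype and co-expression structure real expression data shows.

``generate_clustered``
    Unlabelled Gaussian blobs in a low-dimensional latent space, embedded
    into d observed dimensions by a random linear map plus noise, with the
    true cluster labels returned — the ground truth for evaluating the
    fuzzy-clustering partitioner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import DataMatrix


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic draw.

    effect_size is the class-mean shift in units of noise_sd;
    cluster_separation is the latent-space distance between blob centers,
    also in noise-sd units.
    """

    n_samples: int = 200
    n_features: int = 500
    n_informative: int = 30
    effect_size: float = 1.5
    n_classes: int = 2
    class_balance: tuple[float, ...] | None = None
    n_latent_clusters: int = 3
    cluster_separation: float = 8.0
    noise_sd: float = 1.0
    feature_correlation: float = 0.0
    equalize_variance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_balance is None:
            self.class_balance = tuple([1.0 / self.n_classes] * self.n_classes)
        bal = np.asarray(self.class_balance, dtype=float)
        if len(bal) != self.n_classes or np.any(bal < 0) or abs(bal.sum() - 1) > 1e-9:
            raise ValueError("class_balance must be non-negative and sum to 1")
        if not 0 <= self.feature_correlation < 1:
            raise ValueError("feature_correlation must lie in [0, 1)")


def _class_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Deterministic per-class counts (largest-remainder), shuffled."""
    bal = np.asarray(spec.class_balance, dtype=float)
    counts = np.floor(bal * spec.n_samples).astype(int)
    rem = spec.n_samples - counts.sum()
    order = np.argsort(-(bal * spec.n_samples - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(labels)
    return labels


def generate_classification(spec: SyntheticSpec) -> tuple[DataMatrix, np.ndarray]:
    """Draw a labelled matrix; returns (matrix, informative feature indices)."""
    if spec.n_informative > spec.n_features:
        raise ValueError("n_informative exceeds n_features")
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    y = _class_labels(spec, rng)

    informative = np.sort(rng.choice(d, size=spec.n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)

    X = rng.normal(0.0, spec.noise_sd, size=(n, d))
    if spec.feature_correlation > 0 and spec.n_informative > 0:
        rho = spec.feature_correlation
        shared = rng.normal(0.0, spec.noise_sd, size=(n, 1))
        X[:, informative] = (
            np.sqrt(rho) * shared + np.sqrt(1 - rho) * X[:, informative]
        )
    # class-mean shift on informative features only
    shift = spec.effect_size * spec.noise_sd
    if spec.equalize_variance and spec.n_informative > 0:
        # shrink within-class noise so the marginal variance matches the
        # noise features: class signal then hides from variance filters
        bal = np.asarray(spec.class_balance)
        m = np.arange(spec.n_classes) * shift
        between = float(np.sum(bal * m**2) - np.sum(bal * m) ** 2)
        within = math.sqrt(max(spec.noise_sd**2 - between,
                               (0.1 * spec.noise_sd) ** 2))
        X[:, informative] *= within / spec.noise_sd
    for c in range(spec.n_classes):
        X[np.ix_(y == c, informative)] += c * shift * signs

    # latent cluster structure, independent of class, spread over all features
    if spec.n_latent_clusters >= 2 and spec.cluster_separation > 0:
        q = min(max(5, spec.n_latent_clusters), d)
        centers = _separated_centers(spec.n_latent_clusters, q,
                                     spec.cluster_separation * spec.noise_sd, rng)
        z = centers[rng.integers(spec.n_latent_clusters, size=n)]
        embed = rng.normal(0.0, 1.0, size=(q, d)) / np.sqrt(d)
        X += z @ embed

    labels = np.array([f"class{c}" for c in y])
    dm = DataMatrix(
        values=X,
        feature_names=[f"f{j}" for j in range(d)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
    )
    return dm, informative


def _separated_centers(k: int, q: int, separation: float,
                       rng: np.random.Generator) -> np.ndarray:
    """k latent centers with every pairwise distance equal to ``separation``.

    Orthonormalized random directions scaled by separation/sqrt(2); random
    directions alone can land nearly parallel and collapse the separation.
    """
    if q < k:
        raise ValueError("latent dimension must be >= number of clusters")
    raw = rng.normal(0.0, 1.0, size=(q, k))
    ortho, _ = np.linalg.qr(raw)
    return ortho.T * (separation / np.sqrt(2.0))


def generate_clustered(spec: SyntheticSpec) -> tuple[DataMatrix, np.ndarray]:
    """Draw latent Gaussian blobs embedded in d dimensions.

    Returns (matrix, true cluster labels).  With ``cluster_separation`` 0
    all blobs coincide (a null draw).
    """
    if spec.n_latent_clusters < 2:
        raise ValueError("need at least 2 latent clusters")
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.n_latent_clusters
    q = min(max(5, k), d)
    if spec.cluster_separation > 0:
        centers = _separated_centers(k, q, spec.cluster_separation * spec.noise_sd,
                                     rng)
    else:
        centers = np.zeros((k, q))
    cluster = rng.integers(k, size=n)
    latent = centers[cluster] + rng.normal(0.0, spec.noise_sd, size=(n, q))

    embed = rng.normal(0.0, 1.0, size=(q, d)) / np.sqrt(q)
    X = latent @ embed + rng.normal(0.0, spec.noise_sd, size=(n, d))

    # alternate two labels so the matrix is usable by label-requiring stages
    labels = np.array([f"class{i % 2}" for i in range(n)])
    dm = DataMatrix(
        values=X,
        feature_names=[f"f{j}" for j in range(d)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
    )
    return dm, cluster
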