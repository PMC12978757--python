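"""Improved deep fuzzy clustering (IDFC) for data partitioning.

The partitioner embeds the normalized samples with a small autoencoder and
refines a fuzzy clustering of the latent codes by joint gradient descent on

    L = L_rec + eta1 * KL(T || U) + eta2 * sum_{x,u} ||z_x - z_u||^2 Aff_{x,u}

where L_rec is the mean squared reconstruction error plus an L2 weight
penalty, U is the fuzzy membership of the latent codes to the cluster
centers, T is the sharpened (self-training) target distribution derived
from U, and Aff is a hybrid Gaussian/exponential kernel affinity restricted
to pairs sharing a pseudo-label.  Membership uses a fuzzy-c-means-style
inverse-distance rule with a mu-weighted between-cluster separation term.

Everything is plain numpy: the networks are tiny (input -> 64 -> latent,
mirrored decoder, tanh hidden layers, linear outputs) and the gradients of
the full objective, including the membership term's dependence on latent
codes and centers, are derived analytically (and verified against finite
differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

_D_FLOOR = 1e-12  # clamp for the membership distance term before the negative power


@dataclass
class KernelSpec:
    """Hybrid Gaussian/exponential kernel: alpha*k_gauss + (1-alpha)*k_exp."""

    alpha_kernel: float = 0.5
    sigma: float | str = "median"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_kernel <= 1.0:
            raise ValueError("alpha_kernel must lie in [0, 1]")
        if not isinstance(self.sigma, str) and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class IDFCConfig:
    n_clusters: int = 3
    batch_size: int | None = None  # None -> min(256, n)
    latent_dim: int = 10
    hidden_dim: int = 64
    fuzzifier: float = 2.0
    balance: float = 0.1       # mu: between-cluster separation weight
    eta1: float = 0.1          # KL loss weight
    eta2: float = 1e-4         # affinity loss weight (raw pair-sum: scales with b^2)
    delta: float = 1.0         # affinity exponent
    kernel: KernelSpec = field(default_factory=KernelSpec)
    weight_decay: float = 1e-4
    epochs: int = 100
    pretrain_epochs: int = 100
    learning_rate: float = 1e-3
    target_update_interval: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must exceed 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


class AutoencoderModel:
    """input -> hidden (tanh) -> latent (linear) -> hidden (tanh) -> output."""

    def __init__(self, n_inputs: int, hidden_dim: int, latent_dim: int,
                 rng: np.random.Generator):
        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        self.n_inputs = n_inputs
        self.W1 = glorot(n_inputs, hidden_dim)
        self.b1 = np.zeros(hidden_dim)
        self.W2 = glorot(hidden_dim, latent_dim)
        self.b2 = np.zeros(latent_dim)
        self.W3 = glorot(latent_dim, hidden_dim)
        self.b3 = np.zeros(hidden_dim)
        self.W4 = glorot(hidden_dim, n_inputs)
        self.b4 = np.zeros(n_inputs)

    @property
    def encoder_layer_sizes(self) -> list[int]:
        return [self.W1.shape[0], self.W1.shape[1], self.W2.shape[1]]

    def encode(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1 + self.b1) @ self.W2 + self.b2

    def forward(self, X: np.ndarray):
        H1 = np.tanh(X @ self.W1 + self.b1)
        Z = H1 @ self.W2 + self.b2
        H2 = np.tanh(Z @ self.W3 + self.b3)
        Xhat = H2 @ self.W4 + self.b4
        return H1, Z, H2, Xhat

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[3]

    def weight_norm(self) -> float:
        return float(sum((W ** 2).sum() for W in (self.W1, self.W2, self.W3, self.W4)))

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2,
                self.W3, self.b3, self.W4, self.b4]


@dataclass
class FuzzyState:
    latent: np.ndarray          # n x latent_dim
    centers: np.ndarray         # C x latent_dim
    membership: np.ndarray      # n x C, rows sum to 1
    target: np.ndarray          # n x C, rows sum to 1
    affinity: np.ndarray        # n x n, symmetric
    pseudo_labels: np.ndarray   # n, argmax membership
    sigma: float                # resolved kernel width
    loss_trajectory: list[float] = field(default_factory=list)


@dataclass
class PartitionSet:
    assignment: np.ndarray
    partitions: list[np.ndarray]

    def __post_init__(self) -> None:
        seen = np.concatenate(self.partitions) if self.partitions else np.array([], int)
        if len(seen) != len(self.assignment) or len(np.unique(seen)) != len(seen):
            raise ValueError("partitions must disjointly cover all samples")


# ---------------------------------------------------------------- kernels

def hybrid_kernel(a: np.ndarray, b: np.ndarray, spec: KernelSpec) -> float:
    """alpha*exp(-||a-b||^2 / 2 sigma^2) + (1-alpha)*exp(-||a-b|| / sigma)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("vector length mismatch")
    sigma = spec.sigma
    if isinstance(sigma, str):
        raise ValueError("sigma sentinel not resolved; provide a numeric sigma")
    r = float(np.linalg.norm(a - b))
    al = spec.alpha_kernel
    return al * np.exp(-r * r / (2.0 * sigma * sigma)) + (1 - al) * np.exp(-r / sigma)


def _hybrid_gram(Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    sigma = spec.sigma
    sq = np.sum(Z * Z, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T, 0.0)
    np.fill_diagonal(d2, 0.0)  # exact: the Gram trick leaves float residue
    r = np.sqrt(d2)
    al = spec.alpha_kernel
    return al * np.exp(-d2 / (2.0 * sigma * sigma)) + (1 - al) * np.exp(-r / sigma)


def resolve_sigma(Z: np.ndarray, spec: KernelSpec) -> KernelSpec:
    """Resolve the 'median' sentinel to the median nonzero pairwise distance."""
    if not isinstance(spec.sigma, str):
        return spec
    if spec.sigma != "median":
        raise ValueError(f"unknown sigma sentinel {spec.sigma!r}")
    n = Z.shape[0]
    iu = np.triu_indices(n, k=1)
    d = np.sqrt(np.maximum(
        np.sum(Z * Z, 1)[:, None] + np.sum(Z * Z, 1)[None, :] - 2 * Z @ Z.T, 0.0
    ))[iu]
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return replace(spec, sigma=med if med > 0 else 1.0)


# ---------------------------------------------------------------- losses

def reconstruction_loss(model: AutoencoderModel, X: np.ndarray,
                        weight_decay: float) -> float:
    """(1/b) sum ||R(x) - x||^2 + weight_decay * sum W^2."""
    X = np.asarray(X, float)
    if X.shape[1] != model.n_inputs:
        raise ValueError("input dimension mismatch")
    Xhat = model.reconstruct(X)
    return float(np.sum((Xhat - X) ** 2) / X.shape[0]
                 + weight_decay * model.weight_norm())


def _membership_distances(latent, centers, balance):
    """D_{x,y} = ||z_x - c_y||^2 - mu * ||c_y - cbar||^2 / sum_v ||c_v - cbar||^2."""
    diff = latent[:, None, :] - centers[None, :, :]
    d2 = np.sum(diff * diff, axis=2)
    cbar = centers.mean(axis=0)
    a = np.sum((centers - cbar) ** 2, axis=1)
    total = a.sum()
    sep = a / total if total > 0 else np.zeros_like(a)
    return d2 - balance * sep, d2


def compute_membership(latent: np.ndarray, centers: np.ndarray,
                       fuzzifier: float = 2.0, balance: float = 0.0) -> np.ndarray:
    """Fuzzy membership of each latent code to each center.

    Inverse-power rule: U_{x,y} proportional to D_{x,y}^{-1/(fuz-1)} with
    D the squared distance minus the mu-weighted normalized between-cluster
    separation of the target center.  A point exactly on a center gets the
    one-hot limit membership; ties (several zero distances) split equally.
    """
    latent = np.atleast_2d(np.asarray(latent, float))
    centers = np.atleast_2d(np.asarray(centers, float))
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    if centers.shape[0] >= 2 and np.allclose(centers, centers[0], atol=1e-12):
        raise ValueError("all cluster centers identical")
    D, d2 = _membership_distances(latent, centers, balance)
    p = 1.0 / (fuzzifier - 1.0)
    Dc = np.maximum(D, _D_FLOOR)
    G = Dc ** (-p)
    U = G / G.sum(axis=1, keepdims=True)
    on_center = d2 <= 1e-24
    rows = np.any(on_center, axis=1)
    if np.any(rows):
        U[rows] = on_center[rows] / on_center[rows].sum(axis=1, keepdims=True)
    return np.clip(U, 0.0, 1.0)


def compute_target(membership: np.ndarray) -> np.ndarray:
    """Sharpened self-training target: square, divide by column mass, renormalize rows."""
    U = np.asarray(membership, float)
    if not np.allclose(U.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("membership rows must sum to 1")
    colmass = U.sum(axis=0)
    num = np.zeros_like(U)
    nz = colmass > 0
    num[:, nz] = U[:, nz] ** 2 / colmass[nz]
    denom = num.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("target undefined: a row has zero mass in every cluster")
    return num / denom


def kl_loss(target: np.ndarray, membership: np.ndarray) -> float:
    """KL(T || U) with the 0*log(0/q)=0 convention; U clamped at 1e-12."""
    T = np.asarray(target, float)
    U = np.asarray(membership, float)
    if T.shape != U.shape:
        raise ValueError("shape mismatch")
    if np.any((U < 1e-12) & (T > 0)):
        warnings.warn("membership entries clamped at 1e-12 in KL", RuntimeWarning)
    Uc = np.maximum(U, 1e-12)
    mask = T > 0
    return float(np.sum(T[mask] * np.log(T[mask] / Uc[mask])))


def compute_affinity(latent: np.ndarray, pseudo_labels: np.ndarray,
                     spec: KernelSpec, delta: float = 1.0) -> np.ndarray:
    """Aff_{x,u} = hybrid_kernel(z_x, z_u)^delta if same pseudo-label else 0."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    Z = np.asarray(latent, float)
    ell = np.asarray(pseudo_labels)
    K = _hybrid_gram(Z, spec) ** delta
    same = ell[:, None] == ell[None, :]
    Aff = np.where(same, K, 0.0)
    np.fill_diagonal(Aff, 1.0)
    return Aff


def total_loss(model: AutoencoderModel, X: np.ndarray, state: FuzzyState,
               config: IDFCConfig) -> float:
    """Reconstruction + eta1*KL + eta2*affinity-weighted latent compactness."""
    rec = reconstruction_loss(model, X, config.weight_decay)
    kl = kl_loss(state.target, state.membership)
    Z = state.latent
    sq = np.sum(Z * Z, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T
    aff_term = float(np.sum(np.maximum(d2, 0.0) * state.affinity))
    return rec + config.eta1 * kl + config.eta2 * aff_term


# ---------------------------------------------------------------- gradients

def _grad_step(model, X, centers, T, Aff, config, sigma):
    """One gradient step on the joint loss over network weights and centers.

    T (target), pseudo-labels and Aff are held fixed for the step (DEC-style
    alternation); the membership's dependence on latent codes and centers is
    differentiated exactly, including the mu-term through the center mean.
    Returns the loss value at the pre-step parameters.
    """
    b = X.shape[0]
    gamma = config.weight_decay
    eta1, eta2 = config.eta1, config.eta2
    mu = config.balance
    p = 1.0 / (config.fuzzifier - 1.0)

    H1, Z, H2, Xhat = model.forward(X)

    # --- loss pieces
    rec = np.sum((Xhat - X) ** 2) / b + gamma * model.weight_norm()
    D, d2 = _membership_distances(Z, centers, mu)
    Dc = np.maximum(D, _D_FLOOR)
    G = Dc ** (-p)
    S = G.sum(axis=1, keepdims=True)
    U = G / S
    Uc = np.maximum(U, 1e-12)
    mask = T > 0
    kl = float(np.sum(T[mask] * np.log(T[mask] / Uc[mask])))
    sqz = np.sum(Z * Z, axis=1)
    dz2 = np.maximum(sqz[:, None] + sqz[None, :] - 2.0 * Z @ Z.T, 0.0)
    loss = rec + eta1 * kl + eta2 * float(np.sum(dz2 * Aff))

    # --- backward: decoder
    dXhat = (2.0 / b) * (Xhat - X)
    gW4 = H2.T @ dXhat + 2 * gamma * model.W4
    gb4 = dXhat.sum(axis=0)
    dH2 = dXhat @ model.W4.T
    dpre2 = dH2 * (1.0 - H2 * H2)
    gW3 = Z.T @ dpre2 + 2 * gamma * model.W3
    gb3 = dpre2.sum(axis=0)
    dZ = dpre2 @ model.W3.T

    # --- KL path through membership
    dU = -eta1 * np.where(mask, T / Uc, 0.0)
    dG = (dU - np.sum(dU * U, axis=1, keepdims=True)) / S
    dD = dG * (-p) * G / Dc
    dD[D < _D_FLOOR] = 0.0  # clamped region: flat

    # d2 part: dD/dz_x = 2(z_x - c_y), dD/dc_y = -2(z_x - c_y)
    rowsum = dD.sum(axis=1, keepdims=True)
    dZ += 2.0 * (Z * rowsum - dD @ centers)
    gC = -2.0 * (dD.T @ Z - dD.sum(axis=0)[:, None] * centers)

    # mu separation part: sep_y = a_y / A with a_y = ||c_y - cbar||^2
    cbar = centers.mean(axis=0)
    dev = centers - cbar
    a = np.sum(dev * dev, axis=1)
    A = a.sum()
    if A > 0 and mu != 0:
        c_w = dD.sum(axis=0)                     # sum over x of dL/dD_{x,w}
        # dL/dc_y += -mu * sum_w c_w * dsep_w/dc_y
        # dsep_w/dc_y = (2/A) dev_w (delta_wy - 1/C) - (2 a_w / A^2) dev_y
        C = centers.shape[0]
        # delta_wy picks y=w; the -1/C part is a sum over y broadcast to all w
        term1 = (2.0 / A) * (c_w[:, None] * dev) \
            - (2.0 / (A * C)) * np.sum(c_w[:, None] * dev, axis=0)[None, :]
        term2 = -(2.0 / (A * A)) * float(np.dot(c_w, a)) * dev
        gC += -mu * (term1 + term2)

    # --- affinity path
    deg = Aff.sum(axis=1)
    dZ += eta2 * 4.0 * (deg[:, None] * Z - Aff @ Z)

    # --- encoder
    gW2 = H1.T @ dZ + 2 * gamma * model.W2
    gb2 = dZ.sum(axis=0)
    dH1 = dZ @ model.W2.T
    dpre1 = dH1 * (1.0 - H1 * H1)
    gW1 = X.T @ dpre1 + 2 * gamma * model.W1
    gb1 = dpre1.sum(axis=0)

    lr = config.learning_rate
    for param, grad in zip(model.params(),
                           [gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4]):
        param -= lr * grad
    centers -= lr * gC
    return loss


def _pretrain_step(model, X, config):
    b = X.shape[0]
    gamma = config.weight_decay
    H1, Z, H2, Xhat = model.forward(X)
    loss = np.sum((Xhat - X) ** 2) / b + gamma * model.weight_norm()
    dXhat = (2.0 / b) * (Xhat - X)
    gW4 = H2.T @ dXhat + 2 * gamma * model.W4
    gb4 = dXhat.sum(axis=0)
    dH2 = dXhat @ model.W4.T
    dpre2 = dH2 * (1.0 - H2 * H2)
    gW3 = Z.T @ dpre2 + 2 * gamma * model.W3
    gb3 = dpre2.sum(axis=0)
    dZ = dpre2 @ model.W3.T
    gW2 = H1.T @ dZ + 2 * gamma * model.W2
    gb2 = dZ.sum(axis=0)
    dH1 = dZ @ model.W2.T
    dpre1 = dH1 * (1.0 - H1 * H1)
    gW1 = X.T @ dpre1 + 2 * gamma * model.W1
    gb1 = dpre1.sum(axis=0)
    lr = config.learning_rate
    for param, grad in zip(model.params(),
                           [gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4]):
        param -= lr * grad
    return float(loss)


# ---------------------------------------------------------------- fcm init

def fuzzy_c_means(Z: np.ndarray, n_clusters: int, fuzzifier: float = 2.0,
                  max_iter: int = 100, tol: float = 1e-6,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Classical fuzzy c-means on the rows of Z; returns (centers, membership).

    Centers start at k-means++-style spread data points: a uniform random
    membership init collapses to the degenerate all-uniform fixed point
    (coincident centers at the grand mean) whenever the data are roughly
    balanced, so it is avoided.
    """
    rng = np.random.default_rng(seed)
    n = Z.shape[0]
    centers = np.empty((n_clusters, Z.shape[1]))
    centers[0] = Z[rng.integers(n)]
    for j in range(1, n_clusters):
        d2min = np.min(
            np.sum((Z[:, None, :] - centers[None, :j, :]) ** 2, axis=2), axis=1
        )
        total = d2min.sum()
        probs = d2min / total if total > 0 else np.full(n, 1.0 / n)
        centers[j] = Z[rng.choice(n, p=probs)]
    U = None
    for _ in range(max_iter):
        diff = Z[:, None, :] - centers[None, :, :]
        d2 = np.maximum(np.sum(diff * diff, axis=2), 1e-12)
        G = d2 ** (-1.0 / (fuzzifier - 1.0))
        U_new = G / G.sum(axis=1, keepdims=True)
        if U is not None and np.max(np.abs(U_new - U)) < tol:
            U = U_new
            break
        U = U_new
        Um = U ** fuzzifier
        centers = (Um.T @ Z) / np.maximum(Um.sum(axis=0)[:, None], 1e-12)
    return centers, U


def _ensure_distinct_centers(Z: np.ndarray, centers: np.ndarray,
                             seed: int) -> np.ndarray:
    """Guard against the FCM degenerate fixed point (coincident centers).

    Fuzzy c-means with fuzzifier 2 collapses every center onto the grand
    mean whenever cluster overlap exceeds a threshold; hard k-means does
    not.  When the centers have effectively coincided, they are replaced by
    Lloyd k-means centers on the same codes (deterministic given seed).
    """
    k = centers.shape[0]
    scale = float(np.std(Z)) + 1e-12
    dists = [np.linalg.norm(centers[i] - centers[j])
             for i in range(k) for j in range(i + 1, k)]
    if max(dists) > 1e-4 * scale:
        return centers
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(Z)
    return km.cluster_centers_.astype(float)


# ---------------------------------------------------------------- driver

def fit_idfc(X, config: IDFCConfig):
    """Fit the deep fuzzy partitioner.

    X may be a DataMatrix or an array of normalized values.  Returns
    (AutoencoderModel, FuzzyState, PartitionSet).  The partition fallback
    (merging partitions too small to train a per-partition classifier) uses
    the labels when X is a DataMatrix; with a bare array the raw argmax
    partitions are returned.
    """
    from .data_io import DataMatrix  # local import to avoid cycle at module load

    labels = None
    if isinstance(X, DataMatrix):
        labels = X.labels
        values = X.values
    else:
        values = np.asarray(X, float)
    n, d = values.shape
    if config.n_clusters > n:
        raise ValueError("n_clusters exceeds the number of samples")

    rng = np.random.default_rng(config.seed)
    model = AutoencoderModel(d, config.hidden_dim, config.latent_dim, rng)
    bn = config.batch_size or min(256, n)

    def batches(epoch_rng):
        if bn >= n:  # full batch: fixed order (cached targets stay row-aligned)
            yield np.arange(n)
            return
        order = epoch_rng.permutation(n)
        for start in range(0, n, bn):
            yield order[start:start + bn]

    for _ in range(config.pretrain_epochs):
        for idx in batches(rng):
            _pretrain_step(model, values[idx], config)

    Z = model.encode(values)
    kernel = resolve_sigma(Z, config.kernel)
    centers, _ = fuzzy_c_means(Z, config.n_clusters, config.fuzzifier,
                               seed=config.seed)
    centers = _ensure_distinct_centers(Z, centers.copy(), config.seed)

    trajectory: list[float] = []
    T_cache = aff_cache = None
    for epoch in range(config.epochs):
        for idx in batches(rng):
            Zb = model.encode(values[idx])
            centers = _ensure_distinct_centers(Zb, centers, config.seed)
            if T_cache is None or epoch % max(config.target_update_interval, 1) == 0:
                U = compute_membership(Zb, centers, config.fuzzifier, config.balance)
                T = compute_target(U)
                ell = np.argmax(U, axis=1)
                Aff = compute_affinity(Zb, ell, kernel, config.delta)
            else:
                T, Aff = T_cache, aff_cache
            if bn >= n:
                T_cache, aff_cache = T, Aff
            loss = _grad_step(model, values[idx], centers, T, Aff, config, kernel)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite joint loss at epoch {epoch}; reduce the learning rate"
                )
            trajectory.append(float(loss))

    Z = model.encode(values)
    centers = _ensure_distinct_centers(Z, centers, config.seed)
    U = compute_membership(Z, centers, config.fuzzifier, config.balance)
    T = compute_target(U)
    ell = np.argmax(U, axis=1)
    Aff = compute_affinity(Z, ell, kernel, config.delta)
    state = FuzzyState(latent=Z, centers=centers, membership=U, target=T,
                       affinity=Aff, pseudo_labels=ell,
                       sigma=float(kernel.sigma), loss_trajectory=trajectory)
    parts = assign_partitions(state, labels)
    return model, state, parts


def assign_partitions(state: FuzzyState, labels=None,
                      min_per_class: int = 2) -> PartitionSet:
    """Argmax-membership partitions, merging undersized ones into the
    partition with the nearest center until every partition holds at least
    ``min_per_class`` samples of each class present in the data (when labels
    are given)."""
    U = state.membership
    # ties toward the lower cluster index: argmax keeps first maximum
    assignment = np.argmax(U, axis=1)
    centers = state.centers.copy()
    active = sorted(set(range(centers.shape[0])))

    def ok(cid):
        members = np.where(assignment == cid)[0]
        if members.size == 0:
            return False
        if labels is None:
            return members.size >= min_per_class
        classes = np.unique(labels)
        counts = [(labels[members] == c).sum() for c in classes]
        return all(cnt >= min_per_class for cnt in counts)

    changed = True
    while changed:
        changed = False
        for cid in list(active):
            if len(active) == 1:
                break
            if not ok(cid):
                others = [c for c in active if c != cid]
                dists = [np.linalg.norm(centers[cid] - centers[o]) for o in others]
                target = others[int(np.argmin(dists))]
                assignment[assignment == cid] = target
                # merged center: midpoint keeps later nearest-center merges sensible
                centers[target] = (centers[target] + centers[cid]) / 2.0
                active.remove(cid)
                changed = True
    if len(active) == 1 and not ok(active[0]):
        raise ValueError(
            "cannot form a valid partition: dataset too small or degenerate"
        )
    partitions = [np.where(assignment == cid)[0] for cid in sorted(active)]
    return PartitionSet(assignment=assignment, partitions=partitions)
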