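import copy
import math

import numpy as np
import pytest

from issbec import idfc
from issbec.data_io import apply_minmax, fit_minmax
from issbec.idfc import (
    AutoencoderModel,
    IDFCConfig,
    KernelSpec,
    assign_partitions,
    compute_affinity,
    compute_membership,
    compute_target,
    fit_idfc,
    fuzzy_c_means,
    hybrid_kernel,
    kl_loss,
    reconstruction_loss,
)
from issbec.synthetic import SyntheticSpec, generate_clustered


def purity(assign, truth):
    return sum(np.bincount(truth[assign == c]).max()
               for c in np.unique(assign)) / len(truth)


# ------------------------------------------------------------- kernel

class TestHybridKernel:
    def test_unit_at_zero_distance(self, rng):
        a = rng.normal(size=6)
        for alpha in (0.0, 0.3, 1.0):
            assert hybrid_kernel(a, a, KernelSpec(alpha, 2.0)) == pytest.approx(1.0)

    def test_alpha_one_is_gaussian(self):
        a, b = np.zeros(3), np.ones(3)
        val = hybrid_kernel(a, b, KernelSpec(1.0, 1.5))
        assert val == pytest.approx(math.exp(-3.0 / (2 * 1.5**2)))

    def test_hand_arithmetic(self):
        val = hybrid_kernel(np.array([0.0, 0.0]), np.array([1.0, 0.0]),
                            KernelSpec(0.5, 1.0))
        assert val == pytest.approx(0.5 * math.exp(-0.5) + 0.5 * math.exp(-1.0),
                                    abs=1e-12)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=4), rng.normal(size=4)
            spec = KernelSpec(rng.uniform(), rng.uniform(0.5, 3.0))
            v1, v2 = hybrid_kernel(a, b, spec), hybrid_kernel(b, a, spec)
            assert v1 == pytest.approx(v2, abs=1e-14)
            assert 0 < v1 <= 1

    def test_gram_psd_unit_diag(self, rng):
        for _ in range(10):
            Z = rng.normal(size=(20, 5))
            spec = KernelSpec(rng.uniform(), rng.uniform(0.5, 2.0))
            K = idfc._hybrid_gram(Z, spec)
            np.testing.assert_allclose(K, K.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)
            assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hybrid_kernel(np.zeros(2), np.zeros(3), KernelSpec(0.5, 1.0))
        with pytest.raises(ValueError):
            KernelSpec(0.5, -1.0)


# ------------------------------------------------------------- losses

class TestReconstructionLoss:
    def test_zero_input_gives_weight_penalty(self, rng):
        model = AutoencoderModel(4, 3, 2, rng)
        model.b1[:] = model.b2[:] = 0
        model.b3[:] = model.b4[:] = 0
        X = np.zeros((5, 4))
        # tanh(0)=0 so the network maps 0 -> 0: only the penalty remains
        val = reconstruction_loss(model, X, weight_decay=0.01)
        assert val == pytest.approx(0.01 * model.weight_norm())

    def test_matches_bruteforce(self, rng):
        model = AutoencoderModel(3, 4, 2, rng)
        X = rng.normal(size=(5, 3))
        Xhat = model.reconstruct(X)
        brute = sum(
            sum((Xhat[i, j] - X[i, j]) ** 2 for j in range(3)) for i in range(5)
        ) / 5 + 0.02 * model.weight_norm()
        assert reconstruction_loss(model, X, 0.02) == pytest.approx(brute, rel=1e-12)

    def test_dimension_mismatch(self, rng):
        model = AutoencoderModel(3, 4, 2, rng)
        with pytest.raises(ValueError):
            reconstruction_loss(model, np.zeros((2, 5)), 0.0)


def membership_bruteforce(Z, centers, fuz, mu):
    """Independent loop-based evaluation of the membership rule."""
    n, C = Z.shape[0], centers.shape[0]
    cbar = centers.mean(axis=0)
    a = np.array([np.sum((centers[y] - cbar) ** 2) for y in range(C)])
    A = a.sum()
    U = np.zeros((n, C))
    for x in range(n):
        g = []
        for y in range(C):
            D = np.sum((Z[x] - centers[y]) ** 2) - mu * (a[y] / A if A > 0 else 0)
            g.append(max(D, 1e-12) ** (-1.0 / (fuz - 1)))
        U[x] = np.array(g) / sum(g)
    return U


class TestMembership:
    def test_equidistant_symmetry(self):
        Z = np.array([[0.5]])
        centers = np.array([[0.0], [1.0]])
        U = compute_membership(Z, centers, fuzzifier=2.0, balance=0.0)
        np.testing.assert_allclose(U, [[0.5, 0.5]], atol=1e-12)

    def test_on_center_one_hot(self):
        Z = np.array([[1.0, 2.0]])
        centers = np.array([[1.0, 2.0], [0.0, 0.0], [5.0, 5.0]])
        U = compute_membership(Z, centers, 2.0, 0.1)
        np.testing.assert_allclose(U, [[1.0, 0.0, 0.0]], atol=1e-12)

    def test_matches_bruteforce_with_mu(self):
        Z = np.array([[0.0], [1.0]])
        centers = np.array([[0.25], [0.75]])
        U = compute_membership(Z, centers, 2.0, 0.1)
        np.testing.assert_allclose(
            U, membership_bruteforce(Z, centers, 2.0, 0.1), atol=1e-12
        )

    def test_rows_sum_to_one(self, rng):
        for _ in range(25):
            Z = rng.normal(size=(12, 4))
            centers = rng.normal(size=(3, 4))
            U = compute_membership(Z, centers, rng.uniform(1.5, 3.0),
                                   rng.uniform(0, 0.3))
            np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-10)
            assert U.min() >= 0 and U.max() <= 1

    def test_identical_centers_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            compute_membership(np.zeros((2, 2)), np.ones((3, 2)), 2.0, 0.0)


class TestTarget:
    def test_one_hot_preserved(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(compute_target(U), U, atol=1e-12)

    def test_uniform_stays_uniform(self):
        U = np.full((4, 2), 0.5)
        np.testing.assert_allclose(compute_target(U), U, atol=1e-12)

    def test_matches_bruteforce(self):
        U = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8]])
        col = U.sum(axis=0)
        expected = np.zeros_like(U)
        for x in range(3):
            row = [U[x, y] ** 2 / col[y] for y in range(2)]
            expected[x] = np.array(row) / sum(row)
        np.testing.assert_allclose(compute_target(U), expected, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            raw = rng.dirichlet(np.ones(4), size=10)
            T = compute_target(raw)
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)


class TestKLLoss:
    def test_identity_is_zero(self, rng):
        U = rng.dirichlet(np.ones(3), size=6)
        assert kl_loss(U, U) == pytest.approx(0.0, abs=1e-14)

    def test_closed_form(self):
        T = np.array([[1.0, 0.0], [0.0, 1.0]])
        U = np.full((2, 2), 0.5)
        assert kl_loss(T, U) == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_matches_bruteforce_and_nonnegative(self, rng):
        for _ in range(20):
            T = rng.dirichlet(np.ones(3), size=5)
            U = rng.dirichlet(np.ones(3), size=5)
            brute = sum(
                T[x, y] * math.log(T[x, y] / U[x, y])
                for x in range(5) for y in range(3) if T[x, y] > 0
            )
            val = kl_loss(T, U)
            assert val == pytest.approx(brute, abs=1e-10)
            assert val >= 0


class TestAffinity:
    def test_distinct_labels_identity(self, rng):
        Z = rng.normal(size=(4, 3))
        Aff = compute_affinity(Z, np.arange(4), KernelSpec(0.5, 1.0), 1.0)
        np.testing.assert_allclose(Aff, np.eye(4), atol=1e-12)

    def test_same_label_identical_points(self):
        Z = np.array([[1.0, 1.0], [1.0, 1.0]])
        Aff = compute_affinity(Z, np.array([0, 0]), KernelSpec(0.3, 2.0), 1.0)
        np.testing.assert_allclose(Aff, np.ones((2, 2)), atol=1e-12)

    def test_matches_bruteforce(self, rng):
        Z = rng.normal(size=(4, 2))
        ell = np.array([0, 0, 1, 1])
        spec = KernelSpec(0.4, 1.3)
        Aff = compute_affinity(Z, ell, spec, delta=2.0)
        for x in range(4):
            for u in range(4):
                if x == u:
                    expected = 1.0
                elif ell[x] == ell[u]:
                    expected = hybrid_kernel(Z[x], Z[u], spec) ** 2.0
                else:
                    expected = 0.0
                assert Aff[x, u] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(Aff, Aff.T, atol=1e-12)


class TestTotalLoss:
    def _state(self, rng, model, X, cfg):
        Z = model.encode(X)
        centers = Z[: cfg.n_clusters] + 0.1
        U = compute_membership(Z, centers, cfg.fuzzifier, cfg.balance)
        T = compute_target(U)
        ell = np.argmax(U, axis=1)
        Aff = compute_affinity(Z, ell, cfg.kernel, cfg.delta)
        return idfc.FuzzyState(latent=Z, centers=centers, membership=U,
                               target=T, affinity=Aff, pseudo_labels=ell,
                               sigma=float(cfg.kernel.sigma))

    def test_eta_zero_reduces_to_reconstruction(self, rng):
        X = rng.uniform(size=(10, 5))
        cfg = IDFCConfig(eta1=0.0, eta2=0.0, kernel=KernelSpec(0.5, 1.0))
        model = AutoencoderModel(5, 4, 3, rng)
        state = self._state(rng, model, X, cfg)
        assert idfc.total_loss(model, X, state, cfg) == pytest.approx(
            reconstruction_loss(model, X, cfg.weight_decay), rel=1e-12
        )

    def test_matches_termwise_sum(self, rng):
        X = rng.uniform(size=(8, 4))
        cfg = IDFCConfig(kernel=KernelSpec(0.5, 1.0))
        model = AutoencoderModel(4, 4, 2, rng)
        state = self._state(rng, model, X, cfg)
        rec = reconstruction_loss(model, X, cfg.weight_decay)
        kl = kl_loss(state.target, state.membership)
        aff = sum(
            np.sum((state.latent[x] - state.latent[u]) ** 2) * state.affinity[x, u]
            for x in range(8) for u in range(8)
        )
        expected = rec + cfg.eta1 * kl + cfg.eta2 * aff
        assert idfc.total_loss(model, X, state, cfg) == pytest.approx(
            expected, rel=1e-10
        )


# ------------------------------------------------------------- training

class TestGradients:
    def test_joint_gradient_matches_finite_differences(self, rng):
        n, d = 10, 6
        X = rng.uniform(size=(n, d))
        cfg = IDFCConfig(n_clusters=3, latent_dim=3, hidden_dim=4,
                         learning_rate=1e-6, kernel=KernelSpec(0.5, 1.0))
        model = AutoencoderModel(d, 4, 3, np.random.default_rng(7))
        Z = model.encode(X)
        centers = Z[:3].copy() + 0.3
        U = compute_membership(Z, centers, cfg.fuzzifier, cfg.balance)
        T = compute_target(U)
        Aff = compute_affinity(Z, np.argmax(U, 1), cfg.kernel, cfg.delta)

        def loss_fn(m, c):
            Zl = m.encode(X)
            Ul = compute_membership(Zl, c, cfg.fuzzifier, cfg.balance)
            rec = reconstruction_loss(m, X, cfg.weight_decay)
            sq = np.sum(Zl * Zl, 1)
            d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * Zl @ Zl.T, 0)
            return (rec + cfg.eta1 * kl_loss(T, Ul)
                    + cfg.eta2 * float(np.sum(d2 * Aff)))

        m2, c2 = copy.deepcopy(model), centers.copy()
        before = [p.copy() for p in m2.params()] + [c2.copy()]
        idfc._grad_step(m2, X, c2, T, Aff, cfg, cfg.kernel)
        grads = [(b - a) / cfg.learning_rate
                 for b, a in zip(before, m2.params() + [c2])]

        h = 1e-6
        for pi, grad in enumerate(grads):
            m3, c3 = copy.deepcopy(model), centers.copy()
            P = (m3.params() + [c3])[pi]
            for _, ix in zip(range(4), np.ndindex(*P.shape)):
                orig = P[ix]
                P[ix] = orig + h
                lp = loss_fn(m3, c3)
                P[ix] = orig - h
                lm = loss_fn(m3, c3)
                P[ix] = orig
                fd = (lp - lm) / (2 * h)
                assert grad[ix] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestFitIDFC:
    def test_partition_purity_on_separated_clusters(self):
        purs = []
        for seed in range(3):
            spec = SyntheticSpec(n_samples=120, n_features=40,
                                 n_latent_clusters=3, cluster_separation=8.0,
                                 seed=seed)
            dm, truth = generate_clustered(spec)
            dmn = apply_minmax(fit_minmax(dm), dm)
            _, _, parts = fit_idfc(dmn, IDFCConfig(n_clusters=3, seed=seed))
            purs.append(purity(parts.assignment, truth))
        assert np.mean(purs) >= 0.8

    def test_deterministic_given_seed(self):
        spec = SyntheticSpec(n_samples=40, n_features=15, seed=1)
        dm, _ = generate_clustered(spec)
        dmn = apply_minmax(fit_minmax(dm), dm)
        cfg = IDFCConfig(n_clusters=2, epochs=5, pretrain_epochs=5, seed=3)
        _, s1, p1 = fit_idfc(dmn, cfg)
        _, s2, p2 = fit_idfc(dmn, cfg)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        np.testing.assert_array_equal(s1.latent, s2.latent)

    def test_zero_epochs_reduces_to_fcm_on_latent(self, rng):
        spec = SyntheticSpec(n_samples=50, n_features=12, seed=2)
        dm, _ = generate_clustered(spec)
        dmn = apply_minmax(fit_minmax(dm), dm)
        cfg = IDFCConfig(n_clusters=3, epochs=0, pretrain_epochs=0,
                         balance=0.0, seed=4)
        model, state, _ = fit_idfc(dmn, cfg)
        centers, U = fuzzy_c_means(model.encode(dmn.values), 3,
                                   cfg.fuzzifier, seed=4)
        np.testing.assert_array_equal(np.argmax(state.membership, 1),
                                      np.argmax(U, 1))

    def test_loss_trajectory_non_increasing_frozen_targets(self):
        """Full batch, small step, frozen target/affinity: the joint loss
        must not increase beyond 1e-9 between consecutive steps."""
        spec = SyntheticSpec(n_samples=60, n_features=20, seed=0)
        dm, _ = generate_clustered(spec)
        dmn = apply_minmax(fit_minmax(dm), dm)
        cfg = IDFCConfig(n_clusters=3, epochs=40, pretrain_epochs=50,
                         learning_rate=1e-4, batch_size=60,
                         target_update_interval=10**6, seed=0)
        _, state, _ = fit_idfc(dmn, cfg)
        traj = np.asarray(state.loss_trajectory)
        assert len(traj) == 40
        assert np.all(np.diff(traj) <= 1e-9)

    def test_rows_sum_to_one_after_fit(self):
        spec = SyntheticSpec(n_samples=40, n_features=10, seed=6)
        dm, _ = generate_clustered(spec)
        dmn = apply_minmax(fit_minmax(dm), dm)
        cfg = IDFCConfig(n_clusters=2, epochs=3, pretrain_epochs=3, seed=0)
        _, state, _ = fit_idfc(dmn, cfg)
        np.testing.assert_allclose(state.membership.sum(1), 1.0, atol=1e-10)
        np.testing.assert_allclose(state.target.sum(1), 1.0, atol=1e-10)

    def test_too_many_clusters_rejected(self):
        spec = SyntheticSpec(n_samples=10, n_features=5, seed=0)
        dm, _ = generate_clustered(spec)
        with pytest.raises(ValueError):
            fit_idfc(dm.values, IDFCConfig(n_clusters=11))


class TestAssignPartitions:
    def _state(self, U, centers):
        n = U.shape[0]
        return idfc.FuzzyState(
            latent=np.zeros((n, centers.shape[1])), centers=centers,
            membership=U, target=U, affinity=np.eye(n),
            pseudo_labels=np.argmax(U, 1), sigma=1.0,
        )

    def test_one_hot_assignment(self):
        U = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        centers = np.array([[0.0], [10.0]])
        labels = np.array(["A", "B", "B", "A"])
        # each cluster has only 1 of each class -> merge to a single partition
        parts = assign_partitions(self._state(U, centers), labels)
        assert len(parts.partitions) == 1

    def test_singleton_cluster_merged_to_nearest(self):
        U = np.zeros((9, 3))
        U[:4, 0] = 1
        U[4:8, 1] = 1
        U[8, 2] = 1
        centers = np.array([[0.0], [5.0], [4.0]])
        parts = assign_partitions(self._state(U, centers), labels=None)
        # the singleton at center 4.0 merges into the cluster at 5.0
        assert len(parts.partitions) == 2
        assert np.all(parts.assignment[4:] == parts.assignment[8])

    def test_no_labels_size_rule(self):
        U = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        centers = np.array([[0.0], [1.0]])
        parts = assign_partitions(self._state(U, centers), labels=None)
        assert len(parts.partitions) == 2
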