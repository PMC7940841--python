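import numpy as np
import pytest
from scipy.linalg import subspace_angles

from pl21gpca.graph import build_graph
from pl21gpca.operators import l21_norm, lp_norm
from pl21gpca.solver import (PL21GPCA, SolverConfig, fit_factorization,
                             update_E, update_U, update_V)


def _fit(X, **kwargs):
    """Fit on a genes-by-samples matrix with a given config."""
    cfg = SolverConfig(**kwargs)
    n = X.shape[1]
    kn = cfg.k_neighbors or max(1, round(np.sqrt(n)))
    g = build_graph(X, kn, scheme=cfg.scheme)
    return fit_factorization(X, cfg, g.L)


class TestConfig:
    @pytest.mark.parametrize("bad", [dict(p=1.5), dict(p=0.0), dict(lam=-1),
                                     dict(mu0=0), dict(rho=1.0),
                                     dict(v_update="maybe")])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SolverConfig(**bad)


class TestUpdateE:
    def test_zero_argument_gives_zero(self, rng):
        U = rng.normal(size=(6, 2))
        V, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        X = U @ V.T
        E = update_E(X, U, V, np.zeros_like(X), mu=1.0, p=0.5)
        np.testing.assert_array_equal(E, 0.0)

    def test_scalar_shrink_value(self):
        # X - UV' - Y/mu = 4, p=0.5, mu=1 -> 4 - 4^{-1/2} = 3.5
        X = np.array([[4.0]])
        U = np.zeros((1, 1)); V = np.ones((1, 1)); Y = np.zeros((1, 1))
        assert update_E(X, U, V, Y, 1.0, 0.5)[0, 0] == pytest.approx(3.5)

    def test_sign_flip_of_argument_flips_E(self, rng):
        X = rng.normal(size=(5, 3))
        U = np.zeros((5, 2)); V = np.zeros((3, 2)); Y = np.zeros_like(X)
        E1 = update_E(X, U, V, Y, 2.0, 0.5)
        E2 = update_E(-X, U, V, Y, 2.0, 0.5)
        np.testing.assert_allclose(E2, -E1, atol=1e-14)

    def test_decreases_augmented_lagrangian(self, rng):
        """The E-step cannot increase the separable penalized objective
        sum |e_ij|^p + mu/2 ||E - T||_F^2 that the shrinkage targets."""
        p, mu = 0.5, 3.0
        U = rng.normal(size=(8, 2))
        V, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        X = rng.normal(size=(8, 6)) * 2.0
        Y = rng.normal(size=(8, 6))
        T = X - U @ V.T - Y / mu

        def lagrangian(E):
            return np.sum(np.abs(E) ** p) + mu / 2 * np.linalg.norm(E - T) ** 2

        E_new = update_E(X, U, V, Y, mu, p)
        assert lagrangian(E_new) <= lagrangian(np.zeros_like(T)) + 1e-9
        assert lagrangian(E_new) <= lagrangian(T) + 1e-9
        for _ in range(200):
            E_old = rng.normal(size=(8, 6)) * rng.uniform(0.2, 3.0)
            assert lagrangian(E_new) <= lagrangian(E_old) + 1e-9


class TestUpdateU:
    def test_lambda_zero_is_plain_projection(self, rng):
        H = rng.normal(size=(7, 4))
        V, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        q = rng.uniform(0.5, 2.0, size=7)
        np.testing.assert_allclose(update_U(H, V, q, 0.0, 1.0), H @ V)

    def test_infinite_penalty_kills_rows(self, rng):
        H = rng.normal(size=(5, 3))
        V, _ = np.linalg.qr(rng.normal(size=(3, 2)))
        U = update_U(H, V, np.ones(5), lam=1e12, mu=1.0)
        assert np.max(np.abs(U)) < 1e-9

    def test_scalar_case(self):
        # 1 gene: H=[2,0], V=[[1],[0]], q=1, lam=mu=1 -> (1+2)^{-1} * 2 = 2/3
        U = update_U(np.array([[2.0, 0.0]]), np.array([[1.0], [0.0]]),
                     np.array([1.0]), 1.0, 1.0)
        assert U[0, 0] == pytest.approx(2.0 / 3.0)


class TestUpdateV:
    def test_diagonal_matrix_selects_smallest_eigenvector(self):
        # M = diag(1, 5): alpha/mu * L = diag(1,5), H = 0 -> eigvec (1, 0)
        L = np.diag([1.0, 5.0])
        V = update_V(np.zeros((3, 2)), np.ones(3), L, alpha=1.0, mu=1.0, k=1)
        np.testing.assert_allclose(np.abs(V[:, 0]), [1.0, 0.0], atol=1e-12)
        assert V[0, 0] > 0  # sign fixed

    def test_columns_orthonormal(self, rng):
        H = rng.normal(size=(10, 6))
        L = np.diag(rng.uniform(1, 2, 6))
        V = update_V(H, rng.uniform(0.5, 1.0, 10), L, 2.0, 1.0, 3)
        np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-10)

    def test_no_regularization_recovers_right_singular_subspace(self, rng):
        H = rng.normal(size=(12, 8))
        V = update_V(H, np.ones(12), np.zeros((8, 8)), 0.0, 1.0, 3)
        _, _, Vt = np.linalg.svd(H)
        angles = subspace_angles(V, Vt[:3].T)
        assert np.max(angles) < 1e-10

    def test_rejects_k_above_n(self):
        with pytest.raises(ValueError):
            update_V(np.zeros((3, 2)), np.ones(3), np.zeros((2, 2)), 0.0, 1.0, 5)


class TestFit:
    def test_rank_k_fixture_converges(self, rank4_fixture):
        res = _fit(rank4_fixture, k=4, lam=1.0, alpha=1.0)
        assert res.converged
        assert res.residual_trace[-1] <= 1e-7
        assert np.all(np.diff(np.array(res.residual_trace)[-20:]) <= 1e-6)

    def test_pca_limit_matches_truncated_svd(self, rank4_fixture):
        X = rank4_fixture
        res = _fit(X, k=4, lam=0.0, alpha=0.0)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        angles = subspace_angles(res.V, Vt[:4].T)
        assert np.max(angles) < 1e-6
        err_solver = np.linalg.norm(X - res.U @ res.V.T)
        err_svd = np.linalg.norm(X - (X @ Vt[:4].T) @ Vt[:4])
        assert abs(err_solver - err_svd) < 1e-8

    def test_column_permutation_equivariance(self, rng):
        X = rng.normal(size=(30, 12)) + 3.0
        perm = rng.permutation(12)
        g = build_graph(X, 3)
        cfg = SolverConfig(k=2, lam=5.0, alpha=5.0, max_iter=60)
        res = fit_factorization(X, cfg, g.L)
        gp = build_graph(X[:, perm], 3)
        np.testing.assert_allclose(gp.L, g.L[np.ix_(perm, perm)], atol=1e-12)
        res_p = fit_factorization(X[:, perm], cfg, gp.L)
        np.testing.assert_allclose(res_p.V, res.V[perm], atol=1e-6)

    def test_orthonormal_embedding_every_iteration(self, rank4_fixture):
        res = _fit(rank4_fixture, k=4, lam=10.0, alpha=10.0, max_iter=80)
        assert max(res.ortho_trace) < 1e-8

    def test_row_sparsity_monotone_in_lambda(self, rng):
        X = rng.normal(size=(60, 20))
        X[:10] += 4.0
        counts = []
        for lam in [1.0, 10.0, 100.0, 1000.0]:
            res = _fit(X, k=2, lam=lam, alpha=1.0, max_iter=120)
            counts.append(int(np.sum(np.linalg.norm(res.U, axis=1) > 1e-3)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_embedding_smoothness_monotone_in_alpha(self, rng):
        X = rng.normal(size=(50, 16))
        g = build_graph(X, 4)
        smooth = []
        for alpha in [0.1, 10.0, 1000.0]:
            cfg = SolverConfig(k=2, lam=1.0, alpha=alpha, max_iter=150)
            res = fit_factorization(X, cfg, g.L)
            smooth.append(float(np.trace(res.V.T @ g.L @ res.V)))
        assert all(a >= b - 1e-9 for a, b in zip(smooth, smooth[1:]))

    def test_max_iter_reached_flags_not_converged(self, rng):
        X = rng.normal(size=(20, 10))
        res = _fit(X, k=2, max_iter=3)
        assert not res.converged and res.n_iter == 3

    def test_rejects_nonfinite_input(self):
        X = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            _fit(X, k=2)


class TestEstimatorApi:
    def test_sklearn_contract(self, rank4_fixture):
        from sklearn.base import clone

        est = PL21GPCA(n_components=4, lam=1.0, alpha=1.0, max_iter=60)
        params = est.get_params()
        assert params["n_components"] == 4
        clone(est)  # must be clonable from constructor params
        V = est.fit_transform(rank4_fixture.T)
        assert V.shape == (40, 4)
        np.testing.assert_allclose(V, est.embedding_)
        assert est.components_.shape == (4, 200)

    def test_transform_reconstructs_training_samples(self, rank4_fixture):
        est = PL21GPCA(n_components=4, lam=0.0, alpha=0.0).fit(rank4_fixture.T)
        coords = est.transform(rank4_fixture.T)
        recon = est.inverse_transform(coords)
        np.testing.assert_allclose(recon, rank4_fixture.T, atol=1e-5)

    def test_deterministic_refit(self, rng):
        X = rng.normal(size=(40, 15))
        V1 = PL21GPCA(n_components=3, max_iter=50).fit_transform(X.T)
        V2 = PL21GPCA(n_components=3, max_iter=50).fit_transform(X.T)
        np.testing.assert_array_equal(V1, V2)
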