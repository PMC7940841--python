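"""Robust sparse graph-regularized PCA via an augmented Lagrangian.

The model factorizes a genes-by-samples expression matrix X (p x n,
p >> n) as X ~ U V' with an orthonormal sample embedding V (n x k,
V'V = I) and a gene loading matrix U (p x k), solving

    min_{U,V}  ||X - U V'||_p  +  lam * ||U||_{2,1}  +  alpha * Tr(V' L V)
    s.t.       V'V = I,   0 < p < 1,   lam > 0,   alpha > 0,

where ||.||_p is the elementwise Lp quasi-norm (robust loss), the L2,1
penalty zeroes entire gene rows of U (gene selection), and L is the kNN
graph Laplacian of the samples (local-geometry preservation).

Splitting E = X - U V' gives the augmented Lagrangian

    L(E, U, V; Y, mu) = ||E||_p + mu/2 ||E - X + U V' + Y/mu||_F^2
                        + lam ||U||_{2,1} + alpha Tr(V' L V),

minimized by alternating-direction updates with a growing penalty mu:

  * U-step: with H = X - E - Y/mu and the reweighting diagonal
    q_ii = 1/||u_i||_2, U = (I + (2 lam / mu) Q)^{-1} H V — a row
    scaling of H V.
  * V-step: columns of V are the k eigenvectors of
    (alpha/mu) L - H'A H with smallest eigenvalues, where A is the
    diagonal scaling from the U-step.
  * E-step: generalized shrinkage E = shrink_p(X - U V' - Y/mu, 1/mu).
  * Multiplier: Y <- Y + mu (E - X + U V'); penalty: mu <- rho * mu.

The public interface is a scikit-learn style transformer whose fit
input follows the sklearn convention (samples in rows); the genes-by-
samples orientation used above is handled internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .graph import build_graph
from .operators import l21_norm, lp_norm, reweight_q, shrink_p

__all__ = ["PL21GPCA", "SolverConfig", "FactorResult",
           "update_E", "update_U", "update_V", "fit_factorization"]


@dataclass
class SolverConfig:
    """Hyperparameters of the factorization.

    Attributes
    ----------
    k : int
        Embedding dimension; set to the number of prior sample classes.
    p : float
        Lp-loss exponent in (0, 1).  Smaller p is more outlier-robust.
    lam : float
        L2,1 row-sparsity weight on U (> 0; 0 allowed to disable).
    alpha : float
        Graph-Laplacian embedding weight (> 0; 0 allowed to disable).
    mu0, rho : float
        Initial penalty and its geometric growth factor (mu <- rho*mu).
    mu_max : float
        Cap on mu to avoid overflow under geometric growth.
    k_neighbors : int | None
        Graph neighbor count k'; None means round(sqrt(n_samples)).
    scheme : str
        Graph weighting scheme: heat_kernel, binary, or dot_product.
    sigma : float | None
        Heat-kernel bandwidth; None = mean squared kNN distance.
    v_update : str
        "with_A" uses (alpha/mu) L - H'A H in the V-step (as derived);
        "without_A" drops the diagonal scaling A (uses H'H).
    max_iter, tol : int, float
        Iteration cap and tolerance on the relative constraint residual
        ||E - X + U V'||_F / ||X||_F.
    eps : float
        Row-norm floor in the L2,1 reweighting.
    seed : int | None
        Seed for any stochastic initialization (unused by the default
        deterministic SVD warm start; kept for config round-tripping).
    """

    k: int = 4
    p: float = 0.5
    lam: float = 100.0
    alpha: float = 100.0
    mu0: float = 1e-2
    rho: float = 1.2
    mu_max: float = 1e7
    k_neighbors: int | None = None
    scheme: str = "binary"
    sigma: float | None = None
    v_update: str = "with_A"
    max_iter: int = 500
    tol: float = 1e-7
    eps: float = 1e-8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1); got {self.p}")
        if self.lam < 0 or self.alpha < 0:
            raise ValueError("lam and alpha must be nonnegative")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if self.v_update not in ("with_A", "without_A"):
            raise ValueError(f"unknown v_update {self.v_update!r}")


@dataclass
class FactorResult:
    """Output of the alternating-direction loop.

    U is p x k (gene loadings), V is n x k with V'V = I (sample
    embedding), E is the p x n robust residual, Y the final multiplier.
    ``objective_trace`` records the model objective
    ||X - UV'||_p + lam ||U||_21 + alpha Tr(V'LV) per iteration and
    ``residual_trace`` the relative constraint residual.
    """

    U: NDArray[np.float64]
    V: NDArray[np.float64]
    E: NDArray[np.float64]
    Y: NDArray[np.float64]
    objective_trace: list[float] = field(default_factory=list)
    residual_trace: list[float] = field(default_factory=list)
    ortho_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def update_E(X, U, V, Y, mu: float, p: float) -> NDArray[np.float64]:
    """E-step: generalized shrinkage of the shifted residual."""
    T = X - U @ V.T - Y / mu
    return shrink_p(T, p, 1.0 / mu)


def update_U(H, V, q_diag, lam: float, mu: float) -> NDArray[np.float64]:
    """U-step: row-scaled projection U = (I + (2 lam/mu) Q)^{-1} H V.

    The inverse is diagonal, so it is applied as a per-row scaling
    a_ii = 1 / (1 + (2 lam/mu) q_ii) of H V.
    """
    a = 1.0 / (1.0 + (2.0 * lam / mu) * np.asarray(q_diag))
    return a[:, None] * (H @ V)


def update_V(H, a_diag, L, alpha: float, mu: float, k: int,
             with_A: bool = True) -> NDArray[np.float64]:
    """V-step: k smallest eigenvectors of (alpha/mu) L - H'A H.

    A is the diagonal row scaling carried over from the U-step
    (dropped when ``with_A`` is False).  Column signs are fixed so each
    column's largest-magnitude entry is positive, for determinism.
    """
    n = H.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if with_A:
        HAH = H.T @ (np.asarray(a_diag)[:, None] * H)
    else:
        HAH = H.T @ H
    M = (alpha / mu) * L - HAH
    M = 0.5 * (M + M.T)  # symmetrize against roundoff
    _, vecs = eigh(M, subset_by_index=(0, k - 1))
    # deterministic sign: largest-|entry| positive, first such index on ties
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, j] = -col
    return vecs


def _svd_warm_start(X: NDArray[np.float64], k: int):
    """V0 = top-k right singular vectors of X (uncentered, as the model is)."""
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt[:k].T.copy()
    for j in range(k):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    return V


def fit_factorization(
    X: ArrayLike, config: SolverConfig, L: ArrayLike
) -> FactorResult:
    """Run the alternating-direction loop on a genes-by-samples matrix.

    Update order per sweep: U, V, E, then the multiplier Y and the
    penalty mu.  Initialization: E = 0, Y = 0, V = top-k right singular
    vectors of column-centered X, U = X V.

    Raises ``FloatingPointError`` naming the iteration if non-finite
    values arise mid-loop.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    L = np.asarray(L, dtype=float)
    p_genes, n = X.shape
    if L.shape != (n, n):
        raise ValueError(f"L must be {n}x{n} (one node per sample); got {L.shape}")
    cfg = config
    if not 1 <= cfg.k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}; got {cfg.k}")

    V = _svd_warm_start(X, cfg.k)
    U = X @ V
    E = np.zeros_like(X)
    Y = np.zeros_like(X)
    mu = cfg.mu0
    x_norm = np.linalg.norm(X)
    if x_norm == 0:
        x_norm = 1.0

    result = FactorResult(U=U, V=V, E=E, Y=Y)
    for it in range(1, cfg.max_iter + 1):
        H = X - E - Y / mu
        q = reweight_q(U, cfg.eps)
        U = update_U(H, V, q, cfg.lam, mu)
        a = 1.0 / (1.0 + (2.0 * cfg.lam / mu) * q)
        V = update_V(H, a, L, cfg.alpha, mu, cfg.k,
                     with_A=(cfg.v_update == "with_A"))
        E = update_E(X, U, V, Y, mu, cfg.p)
        Y = Y + mu * (E - X + U @ V.T)
        mu = min(cfg.rho * mu, cfg.mu_max)

        if not (np.all(np.isfinite(U)) and np.all(np.isfinite(V))
                and np.all(np.isfinite(E)) and np.all(np.isfinite(Y))):
            raise FloatingPointError(f"non-finite values at iteration {it}")

        resid = float(np.linalg.norm(E - X + U @ V.T) / x_norm)
        obj = (lp_norm(X - U @ V.T, cfg.p)
               + cfg.lam * l21_norm(U)
               + cfg.alpha * float(np.trace(V.T @ L @ V)))
        result.U, result.V, result.E, result.Y = U, V, E, Y
        result.residual_trace.append(resid)
        result.objective_trace.append(obj)
        result.ortho_trace.append(
            float(np.linalg.norm(V.T @ V - np.eye(cfg.k))))
        result.n_iter = it
        if resid <= cfg.tol:
            result.converged = True
            break
    return result


class PL21GPCA(BaseEstimator, TransformerMixin):
    """Robust sparse graph-regularized PCA transformer.

    Decomposes expression data X (n_samples x n_features after the
    sklearn orientation; genes are features) as X' ~ U V' with an
    orthonormal per-sample embedding V used for clustering and a
    row-sparse gene loading matrix U used for gene ranking.

    Parameters mirror :class:`SolverConfig`; ``n_components`` is the
    embedding dimension k (set to the number of expected sample
    classes) and ``k_neighbors=None`` selects round(sqrt(n_samples)).

    Attributes
    ----------
    embedding_ : ndarray, (n_samples, n_components)
        Orthonormal sample embedding V.
    components_ : ndarray, (n_components, n_features)
        U', analogous to PCA components.
    residual_ : ndarray, (n_features, n_samples)
        Robust residual E.
    graph_ : GraphModel
        The sample kNN graph used for regularization.
    objective_trace_, residual_trace_ : list of float
        Per-iteration diagnostics.
    n_iter_ : int
    converged_ : bool

    Examples
    --------
    >>> from pl21gpca import PL21GPCA, simulate
    >>> X, labels = simulate(noise_variance=0.4, seed=0)
    >>> est = PL21GPCA(n_components=4).fit(X.T)   # samples in rows
    >>> est.embedding_.shape
    (80, 4)
    """

    def __init__(
        self,
        n_components: int = 4,
        p: float = 0.5,
        lam: float = 100.0,
        alpha: float = 100.0,
        mu0: float = 1e-2,
        rho: float = 1.2,
        mu_max: float = 1e7,
        k_neighbors: int | None = None,
        scheme: str = "binary",
        sigma: float | None = None,
        v_update: str = "with_A",
        max_iter: int = 500,
        tol: float = 1e-7,
        eps: float = 1e-8,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.p = p
        self.lam = lam
        self.alpha = alpha
        self.mu0 = mu0
        self.rho = rho
        self.mu_max = mu_max
        self.k_neighbors = k_neighbors
        self.scheme = scheme
        self.sigma = sigma
        self.v_update = v_update
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.random_state = random_state

    def _config(self) -> SolverConfig:
        return SolverConfig(
            k=self.n_components, p=self.p, lam=self.lam, alpha=self.alpha,
            mu0=self.mu0, rho=self.rho, mu_max=self.mu_max,
            k_neighbors=self.k_neighbors, scheme=self.scheme, sigma=self.sigma,
            v_update=self.v_update, max_iter=self.max_iter, tol=self.tol,
            eps=self.eps, seed=self.random_state,
        )

    def fit(self, X: ArrayLike, y=None) -> "PL21GPCA":
        """Fit on X with samples in rows (sklearn orientation)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        cfg = self._config()
        Xg = X.T  # genes x samples
        n = Xg.shape[1]
        kn = cfg.k_neighbors
        if kn is None:
            kn = max(1, min(n - 1, round(np.sqrt(n))))
        graph = build_graph(Xg, kn, scheme=cfg.scheme, sigma=cfg.sigma)
        res = fit_factorization(Xg, cfg, graph.L)
        self.graph_ = graph
        self.embedding_ = res.V
        self.components_ = res.U.T
        self.residual_ = res.E
        self.multiplier_ = res.Y
        self.objective_trace_ = res.objective_trace
        self.residual_trace_ = res.residual_trace
        self.ortho_trace_ = res.ortho_trace
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X: ArrayLike, y=None) -> NDArray[np.float64]:
        """Fit and return the orthonormal sample embedding V."""
        return self.fit(X).embedding_

    def transform(self, X: ArrayLike) -> NDArray[np.float64]:
        """Project new samples onto the fitted gene loadings.

        Least-squares coordinates ``V_new = X U (U'U)^{-1}`` so that
        ``U V_new'`` best reconstructs the new samples; on the training
        data this approximates (not equals) the fitted embedding, which
        additionally satisfies the orthogonality and graph penalties.
        """
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        U = self.components_.T
        return X @ U @ np.linalg.pinv(U.T @ U)

    def inverse_transform(self, V: ArrayLike) -> NDArray[np.float64]:
        """Reconstruct samples-in-rows data from embedding coordinates."""
        check_is_fitted(self, "components_")
        return np.asarray(V, dtype=float) @ self.components_
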