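"""k-nearest-neighbor sample graph, weighting schemes, and Laplacian.

The solver regularizes the sample embedding with the graph Laplacian
L = D - W of a kNN similarity graph built on the samples (columns of the
expression matrix).  Minimizing Tr(V' L V) keeps samples that are close
in the original expression space close in the embedding.

Three classical weighting schemes are supported: heat kernel
``exp(-||x_i - x_j||^2 / sigma)``, binary 0-1, and dot product.  The
directed kNN edge set is symmetrized by union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.neighbors import NearestNeighbors

__all__ = ["GraphModel", "knn_graph", "weight_matrix", "laplacian", "build_graph",
           "export_edge_list"]

SCHEMES = ("heat_kernel", "binary", "dot_product")


@dataclass
class GraphModel:
    """A weighted sample-similarity graph and its Laplacian.

    Attributes
    ----------
    n_nodes : int
        Number of samples (graph vertices).
    k_neighbors : int
        Neighbor count k' used to build the adjacency pattern.
    scheme : str
        One of ``heat_kernel``, ``binary``, ``dot_product``.
    sigma : float | None
        Heat-kernel bandwidth (heat_kernel scheme only).
    W : ndarray, (n, n)
        Symmetric nonnegative weight matrix, zero diagonal.
    D : ndarray, (n, n)
        Diagonal degree matrix, ``d_i = sum_j w_ij``.
    L : ndarray, (n, n)
        Laplacian ``L = D - W``; positive semidefinite, zero row sums.
    """

    n_nodes: int
    k_neighbors: int
    scheme: str
    sigma: float | None
    W: NDArray[np.float64]
    D: NDArray[np.float64] = field(repr=False, default=None)  # type: ignore[assignment]
    L: NDArray[np.float64] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.D is None or self.L is None:
            self.D, self.L = laplacian(self.W)


def knn_graph(X: ArrayLike, k_neighbors: int) -> NDArray[np.intp]:
    """Directed k-nearest-neighbor index sets over samples.

    Parameters
    ----------
    X : array-like, shape (n_genes, n_samples)
        Expression matrix with samples as columns; Euclidean metric.
    k_neighbors : int
        Number of neighbors k', ``1 <= k' < n_samples``.

    Returns
    -------
    ndarray of int, shape (n_samples, k_neighbors)
        Row i holds the k' samples (excluding i) nearest to sample i,
        ties broken by lower sample index.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    n = X.shape[1]
    if not 1 <= k_neighbors < n:
        raise ValueError(f"k_neighbors must satisfy 1 <= k' < n={n}; got {k_neighbors}")
    pts = X.T  # samples as rows
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1, metric="euclidean").fit(pts)
    dist, idx = nn.kneighbors(pts)
    # sklearn's tie order is not guaranteed; re-sort each row by
    # (distance, index) after dropping self, for determinism.
    out = np.empty((n, k_neighbors), dtype=np.intp)
    for i in range(n):
        cand = [(d, j) for d, j in zip(dist[i], idx[i]) if j != i]
        cand.sort()
        out[i] = [j for _, j in cand[:k_neighbors]]
    return out


def weight_matrix(
    neighbors: ArrayLike,
    X: ArrayLike,
    scheme: str = "binary",
    sigma: float | None = None,
) -> NDArray[np.float64]:
    """Weight matrix W on the union-symmetrized kNN edge pattern.

    ``w_ij = exp(-||x_i - x_j||^2 / sigma)`` (heat_kernel), 1 (binary),
    or ``x_i . x_j`` (dot_product) for connected pairs; 0 otherwise.
    An edge is present iff ``i in N(j)`` or ``j in N(i)``.

    If ``sigma`` is None under the heat kernel it defaults to the mean
    squared distance over the directed kNN edges.  Negative dot-product
    weights are clipped to 0 with a warning (the Laplacian requires
    nonnegative weights).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}; got {scheme!r}")
    X = np.asarray(X, dtype=float)
    neighbors = np.asarray(neighbors, dtype=np.intp)
    n = X.shape[1]
    pts = X.T

    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), neighbors.shape[1])
    mask[rows, neighbors.ravel()] = True
    mask |= mask.T  # union symmetrization
    np.fill_diagonal(mask, False)

    if scheme == "binary":
        W = mask.astype(float)
    elif scheme == "dot_product":
        G = pts @ pts.T
        if np.any(G[mask] < 0):
            warnings.warn("negative dot-product weights clipped to 0", stacklevel=2)
        W = np.where(mask, np.clip(G, 0.0, None), 0.0)
    else:  # heat_kernel
        sq = np.sum(pts**2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * pts @ pts.T, 0.0)
        if sigma is None:
            sigma = float(np.mean(d2[rows, neighbors.ravel()]))
            if sigma <= 0:
                sigma = 1.0  # all points coincide
        if sigma <= 0:
            raise ValueError(f"sigma must be positive; got {sigma}")
        W = np.where(mask, np.exp(-d2 / sigma), 0.0)
    return W


def laplacian(W: ArrayLike) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Degree matrix D and combinatorial Laplacian L = D - W.

    Raises if W is not symmetric (within floating tolerance) or has
    negative entries.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    D = np.diag(W.sum(axis=1))
    return D, D - W


def build_graph(
    X: ArrayLike,
    k_neighbors: int,
    scheme: str = "binary",
    sigma: float | None = None,
) -> GraphModel:
    """Convenience: kNN pattern -> weights -> Laplacian in one call."""
    nbrs = knn_graph(X, k_neighbors)
    W = weight_matrix(nbrs, X, scheme=scheme, sigma=sigma)
    return GraphModel(
        n_nodes=W.shape[0], k_neighbors=k_neighbors, scheme=scheme, sigma=sigma, W=W
    )


def export_edge_list(W: ArrayLike, path: str) -> None:
    """Write W's upper-triangular edges as TSV: node_i, node_j, weight."""
    W = np.asarray(W, dtype=float)
    i_idx, j_idx = np.nonzero(np.triu(W, k=1))
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i, j in zip(i_idx, j_idx):
            fh.write(f"{i}\t{j}\t{W[i, j]:.10g}\n")
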