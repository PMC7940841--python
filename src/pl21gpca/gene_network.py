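"""Gene ranking, co-expression network construction, and module analysis.

After the factorization, the row magnitudes of the gene loading matrix
U rank genes by how strongly they are differentially expressed: the
score of gene i is the absolute row sum sum_j |u_ij| (both up- and
down-regulation contribute).  The top-l genes are then connected by
thresholded absolute Pearson correlation across samples, and the
connected components of the resulting graph are reported as
co-expression modules; within a module, high-degree (hub) genes are the
candidates for biologically central roles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["GeneRanking", "GeneNetwork", "rank_genes", "pcc_adjacency",
           "extract_modules", "build_network", "select_gene_count", "hub_genes"]


@dataclass
class GeneRanking:
    """Per-gene scores (absolute row sums of U) and the descending order."""

    scores: NDArray[np.float64]
    order: NDArray[np.intp]

    def top(self, l: int) -> NDArray[np.intp]:
        """Indices of the l highest-scoring genes."""
        if not 1 <= l <= self.order.size:
            raise ValueError(f"l must be in [1, {self.order.size}]; got {l}")
        return self.order[:l]


@dataclass
class GeneNetwork:
    """Thresholded co-expression network over selected genes.

    ``modules`` lists connected components (node index tuples, local to
    ``genes``) sorted by size descending, ties by smallest member;
    isolated nodes (degree 0) are excluded from modules.
    """

    genes: list
    adjacency: NDArray[np.float64]
    threshold: float
    modules: list[tuple[int, ...]] = field(default_factory=list)
    degrees: NDArray[np.intp] = None  # type: ignore[assignment]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))


def rank_genes(U: ArrayLike) -> GeneRanking:
    """Score genes by the absolute row sums of the loading matrix.

    Descending sort; ties broken by lower gene index (stable sort on
    negated scores), so an all-zero U yields the identity order.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    scores = np.sum(np.abs(U), axis=1)
    order = np.argsort(-scores, kind="stable")
    return GeneRanking(scores=scores, order=order)


def pcc_adjacency(R: ArrayLike, threshold: float = 0.8) -> NDArray[np.float64]:
    """Absolute-Pearson adjacency with edge cutoff.

    ``a_ij = |PCC(row_i, row_j)|`` when that value reaches the
    threshold and i != j, else 0.  A zero-variance gene row has no
    defined correlation; it is isolated with a warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1]; got {threshold}")
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    sd = R.std(axis=1)
    degenerate = sd == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene row(s) isolated",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.abs(np.corrcoef(R))
    A[degenerate, :] = 0.0
    A[:, degenerate] = 0.0
    np.fill_diagonal(A, 0.0)
    A[A < threshold] = 0.0
    # numerical symmetry (corrcoef is symmetric up to roundoff)
    return 0.5 * (A + A.T)


def extract_modules(
    adjacency: ArrayLike,
) -> tuple[list[tuple[int, ...]], NDArray[np.intp]]:
    """Connected components (modules) and per-node degrees.

    Modules are sorted by node count descending, ties by smallest
    member index; degree-0 nodes are excluded from modules but still
    appear in the degree vector (with degree 0).
    """
    A = np.atleast_2d(np.asarray(adjacency, dtype=float))
    degrees = np.count_nonzero(A, axis=1).astype(np.intp)
    n_comp, labels = connected_components(csr_matrix(A != 0), directed=False)
    modules = []
    for c in range(n_comp):
        members = tuple(int(i) for i in np.flatnonzero(labels == c))
        if len(members) >= 2:
            modules.append(members)
    modules.sort(key=lambda m: (-len(m), m[0]))
    return modules, degrees


def build_network(
    R: ArrayLike,
    gene_ids: list | None = None,
    threshold: float = 0.8,
) -> GeneNetwork:
    """Adjacency + modules + degrees for the selected-gene submatrix R."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    A = pcc_adjacency(R, threshold)
    modules, degrees = extract_modules(A)
    genes = list(gene_ids) if gene_ids is not None else list(range(R.shape[0]))
    if len(genes) != R.shape[0]:
        raise ValueError("gene_ids length must match the number of rows of R")
    return GeneNetwork(genes=genes, adjacency=A, threshold=threshold,
                       modules=modules, degrees=degrees)


def hub_genes(network: GeneNetwork, n_top: int = 10) -> list[list]:
    """Per-module hub lists: the top ``n_top`` members by degree.

    Ties broken by lower node index; returns gene identifiers.
    """
    hubs = []
    for module in network.modules:
        ranked = sorted(module, key=lambda i: (-int(network.degrees[i]), i))
        hubs.append([network.genes[i] for i in ranked[:n_top]])
    return hubs


def select_gene_count(
    X: ArrayLike,
    labels: ArrayLike,
    candidates,
    fit_fn,
    n_runs: int = 50,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick the selected-gene count l maximizing mean clustering ACC.

    For each candidate l the top-l genes (ranked from a full fit) are
    kept, the model is refit on the submatrix via ``fit_fn(X_sub)``
    (returning an object with ``embedding_`` and ``components_``), and
    the embedding is clustered and scored; the l with the best mean ACC
    wins, ties to the smaller l.

    Parameters
    ----------
    X : ndarray, (n_genes, n_samples)
    labels : prior class labels, length n_samples.
    candidates : iterable of int
        Gene counts to try, e.g. ``range(500, 2001, 100)``.
    fit_fn : callable
        ``fit_fn(X_sub)`` fits on a genes-by-samples submatrix.

    Returns
    -------
    (best_l, scores) where scores maps each candidate to its acc_mean.
    """
    from .evaluation import kmeans_harness  # local import avoids cycle at import time

    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidate list is empty")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).ravel()
    k = len(np.unique(labels))

    full = fit_fn(X)
    ranking = rank_genes(full.components_.T)
    scores: dict[int, float] = {}
    for l in candidates:
        sub = X[np.sort(ranking.top(l))]
        est = fit_fn(sub)
        rep = kmeans_harness(est.embedding_, k, labels, n_runs=n_runs, seed=seed)
        scores[l] = rep.acc_mean
    best_l = max(candidates, key=lambda l: (scores[l], -l))
    return best_l, scores
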