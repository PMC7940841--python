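"""Clustering evaluation: repeated K-means, accuracy, and NMI.

The embedding rows are clustered with K-means under many random
restarts; each run is scored against the prior class labels with

* ACC — the fraction of samples whose cluster label, after the optimal
  cluster-to-class assignment (Hungarian matching on the confusion
  matrix), agrees with the prior label;
* NMI — mutual information of the two partitions (log base 2) divided
  by the larger of their entropies, so identical partitions score 1 and
  empirically independent ones 0.

Because K-means may converge to different local optima per restart,
both the maximum and the mean of each metric over the restarts are
reported; the mean is the more meaningful robustness summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike
from scipy.optimize import linear_sum_assignment
from scipy.special import xlogy
from sklearn.cluster import KMeans
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["ClusteringReport", "accuracy", "nmi", "kmeans_harness"]


@dataclass
class ClusteringReport:
    """ACC/NMI summaries over K-means restarts, as percentages."""

    acc_max: float
    acc_mean: float
    nmi_max: float
    nmi_mean: float
    n_runs: int
    per_run: list[tuple[float, float, int]]  # (ACC, NMI, seed) per restart

    def to_dict(self) -> dict:
        return {
            "acc_max": self.acc_max, "acc_mean": self.acc_mean,
            "nmi_max": self.nmi_max, "nmi_mean": self.nmi_mean,
            "n_runs": self.n_runs,
            "per_run": [list(t) for t in self.per_run],
        }


def _as_labels(x: ArrayLike) -> np.ndarray:
    x = np.asarray(x).ravel()
    if x.size == 0:
        raise ValueError("empty label vector")
    return x


def accuracy(prior: ArrayLike, predicted: ArrayLike) -> float:
    """Clustering accuracy in [0, 1] after optimal label matching.

    Each predicted cluster is mapped to a prior class by the assignment
    that maximizes the total number of matched samples (Hungarian
    algorithm on the contingency table); the accuracy is the matched
    fraction.  Invariant under any bijective relabeling of either
    argument.
    """
    prior, predicted = _as_labels(prior), _as_labels(predicted)
    if prior.shape != predicted.shape:
        raise ValueError(
            f"label vectors differ in length: {prior.size} vs {predicted.size}"
        )
    C = contingency_matrix(prior, predicted)
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].sum()) / prior.size


def nmi(C: ArrayLike, Cp: ArrayLike) -> float:
    """Normalized mutual information of two partitions, in [0, 1].

    MI is computed from the empirical joint distribution with log base
    2 and normalized by max(H(C), H(C')).  The 0/0 case (both
    partitions single-cluster) returns 0.  Symmetric and invariant to
    label permutations; the normalization makes the value independent
    of the logarithm base.
    """
    C, Cp = _as_labels(C), _as_labels(Cp)
    if C.shape != Cp.shape:
        raise ValueError(f"label vectors differ in length: {C.size} vs {Cp.size}")
    n = C.size
    joint = contingency_matrix(C, Cp) / n
    pc = joint.sum(axis=1)
    pcp = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(pc, pcp)[nz])))
    ln2 = np.log(2.0)
    h_c = float(-np.sum(xlogy(pc, pc)) / ln2)
    h_cp = float(-np.sum(xlogy(pcp, pcp)) / ln2)
    denom = max(h_c, h_cp)
    if denom == 0.0:
        return 0.0
    ratio = mi / denom
    # snap roundoff so identical partitions give exactly 1 (MI == H there)
    if abs(ratio - 1.0) < 1e-10:
        return 1.0
    return float(min(1.0, max(0.0, ratio)))


def kmeans_harness(
    V: ArrayLike,
    k: int,
    prior: ArrayLike,
    n_runs: int = 50,
    seed: int = 0,
) -> ClusteringReport:
    """Cluster embedding rows with K-means over seeded restarts.

    Each restart uses a fresh k-means++ initialization with seed
    ``seed + run_index`` and runs to convergence; ACC and NMI versus
    the prior labels are recorded per run and summarized as max/mean
    percentages.  Deterministic for a fixed seed.
    """
    V = np.asarray(V, dtype=float)
    prior = _as_labels(prior)
    if V.ndim != 2 or V.shape[0] != prior.size:
        raise ValueError("V must be (n_samples, k) aligned with prior labels")
    if k > V.shape[0]:
        raise ValueError(f"k={k} exceeds n_samples={V.shape[0]}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    per_run: list[tuple[float, float, int]] = []
    for r in range(n_runs):
        run_seed = seed + r
        pred = KMeans(
            n_clusters=k, init="k-means++", n_init=1, random_state=run_seed
        ).fit_predict(V)
        per_run.append((accuracy(prior, pred), nmi(prior, pred), run_seed))

    accs = np.array([a for a, _, _ in per_run])
    nmis = np.array([m for _, m, _ in per_run])
    return ClusteringReport(
        acc_max=float(accs.max()) * 100.0,
        acc_mean=float(accs.mean()) * 100.0,
        nmi_max=float(nmis.max()) * 100.0,
        nmi_mean=float(nmis.mean()) * 100.0,
        n_runs=n_runs,
        per_run=per_run,
    )
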