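"""Norm evaluations and proximal / reweighting operators.

These are the scalar building blocks of the augmented-Lagrangian solver:
the Lp quasi-norm used as a robust loss, the L2,1 norm that induces
row-sparsity of the gene loading matrix, the generalized shrinkage
operator that approximates the Lp proximal step, and the diagonal
reweighting matrix used to solve the L2,1-penalized least-squares
subproblem by iterative reweighting.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["lp_norm", "l21_norm", "shrink_p", "reweight_q"]


def lp_norm(M: ArrayLike, p: float) -> float:
    """Lp quasi-norm ``(sum |m_ij|^p)^(1/p)`` for an exponent ``0 < p < 1``.

    For p below 1 this is not a true norm (the triangle inequality
    fails) but it promotes sparser solutions than the L1 norm and is
    less sensitive to large outliers than the squared Frobenius loss.

    Parameters
    ----------
    M : array-like
        Any array; entries are treated elementwise.
    p : float
        Exponent, strictly between 0 and 1.

    Returns
    -------
    float
        Nonnegative quasi-norm value.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1); got {p}")
    M = np.asarray(M, dtype=float)
    s = float(np.sum(np.abs(M) ** p))
    return s ** (1.0 / p)


def l21_norm(M: ArrayLike) -> float:
    """L2,1 norm: the sum of the Euclidean norms of the rows.

    Penalizing this norm drives entire rows of a matrix to zero, which
    is what makes it a feature (gene) selection penalty when applied to
    a genes-by-components loading matrix.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    return float(np.sum(np.linalg.norm(M, axis=1)))


def shrink_p(T: ArrayLike, p: float, delta: float) -> NDArray[np.float64]:
    """Generalized shrinkage ``sign(t) * max{0, |t| - delta*|t|^(p-1)}``.

    An elementwise thresholder approximating the proximal operator of
    the Lp quasi-norm.  At ``p = 1`` it reduces exactly to classical
    soft thresholding; for ``p < 1`` the threshold is adaptive: an entry
    survives iff ``|t|^(2-p) > delta``, so small entries are suppressed
    more aggressively than under the L1 prox.  ``t = 0`` maps to 0 (the
    ``t/|t|`` factor is taken as 0 there).

    Parameters
    ----------
    T : array-like
        Input matrix (or scalar) to shrink, elementwise.
    p : float
        Exponent in (0, 1]; ``p = 1`` is permitted as the soft-threshold
        degenerate case.
    delta : float
        Threshold, > 0 (equal to 1/mu inside the solver).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1]; got {p}")
    if delta <= 0:
        raise ValueError(f"delta must be positive; got {delta}")
    T = np.asarray(T, dtype=float)
    absT = np.abs(T)
    with np.errstate(divide="ignore"):
        # |t|^(p-1) -> inf at t=0 for p<1; the max{0, .} then yields 0,
        # matching the t/|t| := 0 convention.
        shrunk = absT - delta * np.where(absT > 0, absT ** (p - 1.0), np.inf)
    return np.sign(T) * np.maximum(0.0, shrunk)


def reweight_q(U: ArrayLike, eps: float = 1e-8) -> NDArray[np.float64]:
    """Diagonal of the reweighting matrix Q with ``q_ii = 1 / ||u_i||_2``.

    Q linearizes the L2,1 penalty around the current iterate so that the
    loading-matrix update becomes a (row-wise) scaled least squares.
    Rows with norm below ``eps`` are floored at ``eps`` to keep Q finite
    while preserving the strong shrinkage pressure on near-zero rows.

    Returns the diagonal as a 1-D array (the full Q is never formed).
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive; got {eps}")
    U = np.atleast_2d(np.asarray(U, dtype=float))
    row_norms = np.linalg.norm(U, axis=1)
    return 1.0 / np.maximum(row_norms, eps)
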