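"""Kernel-based Jointly Smooth Functions (JSF).

Given two datasets with aligned rows — here, time-delayed output observations
x1 and the generating parameter vectors x2 — JSF extraction finds functions
that are simultaneously smooth over both.  Each dataset contributes an
orthonormal basis of Gaussian-kernel eigenvectors; the singular value
decomposition of the concatenated bases [U1 U2] scores every left singular
vector by how close it is to both spans: a function lying exactly in the
intersection has singular value sqrt(2), one visible to a single dataset has
1, and the scores live in [0, sqrt(2)].  Functions with scores near sqrt(2)
are jointly smooth — for parameter/output pairs, these are the effective
parameter combinations the output actually depends on.

The complement is equally useful: eigenfunctions of the *parameter* kernel
projected orthogonal to the span of the retained JSFs are smooth functions
of the parameters that the output does not see — the redundant parameter
combinations that parameterize level sets of constant behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist

from .dmaps import choose_epsilon

__all__ = ["JSFBasis", "jsf_extract", "jsf_redundant_combinations", "jsf_score_gap"]

SQRT2 = float(np.sqrt(2.0))


@dataclass
class JSFBasis:
    """JSF decomposition of a paired dataset.

    ``functions`` holds M jointly smooth functions (columns, orthonormal over
    the samples) with nonincreasing ``scores`` in [0, sqrt(2)].  ``U1`` and
    ``U2`` are the per-dataset kernel eigenbases; ``epsilons`` the kernel
    scales used.
    """

    functions: np.ndarray
    scores: np.ndarray
    U1: np.ndarray
    U2: np.ndarray
    sig1: np.ndarray
    sig2: np.ndarray
    epsilons: tuple
    X1: np.ndarray
    X2: np.ndarray

    def nonconstant_indices(self, tol: float = 0.5):
        """Columns that are not the shared constant function.

        An orthonormal column over n samples has variance 1/n when centered;
        a (near-)constant column concentrates its norm in the mean instead.
        """
        n = self.functions.shape[0]
        variances = self.functions.var(axis=0)
        return [int(j) for j in range(self.functions.shape[1]) if variances[j] > tol / n]


def _kernel_basis(X: np.ndarray, d: int, epsilon: float | None):
    if epsilon is None:
        epsilon = choose_epsilon(pdist(X))
    K = np.exp(-cdist(X, X) ** 2 / epsilon)
    n = K.shape[0]
    sig, U = eigh(K, subset_by_index=(n - d, n - 1))
    order = np.argsort(sig)[::-1]
    return U[:, order], np.clip(sig[order], 0.0, None), float(epsilon)


def jsf_extract(
    X1: np.ndarray,
    X2: np.ndarray,
    d1: int = 64,
    d2: int = 64,
    M: int = 25,
    epsilons: tuple = (None, None),
) -> JSFBasis:
    """Extract M jointly smooth functions from the paired datasets X1, X2.

    Each dataset gets a ``d_i``-dimensional orthonormal Gaussian-kernel
    eigenbasis (median-rule scale unless given); the left singular vectors of
    the horizontal concatenation [U1 U2], ordered by singular value, are the
    candidate functions.  The leading ones (scores near sqrt(2)) are jointly
    smooth.  Deterministic: singular-vector signs are fixed so the first
    significant entry is positive.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n = X1.shape[0]
    if X2.shape[0] != n:
        raise ValueError("X1 and X2 must have the same number of rows")
    if not (0 < d1 < n and 0 < d2 < n):
        raise ValueError("basis sizes d1, d2 must lie in (0, n)")
    if M > d1 + d2:
        raise ValueError(f"cannot extract M={M} functions from a {d1 + d2}-dim basis")
    U1, sig1, eps1 = _kernel_basis(X1, d1, epsilons[0])
    U2, sig2, eps2 = _kernel_basis(X2, d2, epsilons[1])
    F, s, _ = np.linalg.svd(np.hstack([U1, U2]), full_matrices=False)
    F, s = F[:, :M], np.clip(s[:M], 0.0, SQRT2)
    for j in range(F.shape[1]):  # deterministic signs
        col = F[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
        if nz.size and col[nz[0]] < 0:
            F[:, j] = -col
    return JSFBasis(functions=F, scores=s, U1=U1, U2=U2, sig1=sig1, sig2=sig2,
                    epsilons=(eps1, eps2), X1=X1, X2=X2)


def jsf_score_gap(scores: np.ndarray, threshold: float = 0.9) -> int:
    """Number of retained JSFs: scores at or above ``threshold * sqrt(2)``.

    If every score clears the threshold the two datasets share their whole
    span (e.g. X1 == X2); everything is retained with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    M = int(np.sum(scores >= threshold * SQRT2))
    if M == scores.size:
        warnings.warn(
            "all candidate functions are jointly smooth; the two datasets "
            "may be redundant copies of each other",
            RuntimeWarning,
            stacklevel=2,
        )
    return M


def jsf_redundant_combinations(
    basis: JSFBasis, n_retained: int | None = None, rel_tol: float = 1e-6
) -> np.ndarray:
    """Smooth functions of X2 that the output does not see.

    The X2 kernel eigenbasis, with each eigenfunction weighted by its kernel
    eigenvalue (so smoother functions carry more norm), is projected
    orthogonal to the span of the ``n_retained`` leading JSFs (default: the
    score-gap count) and re-orthonormalized by SVD.  The leading columns are
    therefore the *smoothest* functions of the parameters that the output
    does not see — the redundant parameter combinations.  Each column is
    orthogonal (<= 1e-8 inner product) to every retained JSF; directions
    whose weighted residual falls below ``rel_tol`` of the leading one are
    dropped, so if the retained JSFs exhaust the parameter basis the result
    is empty.
    """
    if n_retained is None:
        n_retained = jsf_score_gap(basis.scores)
    F = basis.functions[:, :n_retained]
    W2 = basis.U2 * (basis.sig2 / max(basis.sig2[0], 1e-300))
    resid = W2 - F @ (F.T @ W2)
    Q, s, _ = np.linalg.svd(resid, full_matrices=False)
    # the leading weighted column has unit norm, so the tolerance is absolute:
    # if the retained JSFs exhaust the X2 span, nothing survives
    keep = s > rel_tol
    Q = Q[:, keep]
    # second projection pass tightens orthogonality lost to round-off
    Q -= F @ (F.T @ Q)
    norms = np.linalg.norm(Q, axis=0, keepdims=True)
    Q /= np.where(norms > 0, norms, 1.0)
    for j in range(Q.shape[1]):
        col = Q[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
        if nz.size and col[nz[0]] < 0:
            Q[:, j] = -col
    return Q
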