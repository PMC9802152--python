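"""Diffusion Maps, parsimonious eigenvector selection, and Nystrom extension.

The central construction: given a point cloud, build the Gaussian kernel
W_ij = exp(-||x_i - x_j||^2 / eps), density-normalize it with exponent alpha
(alpha = 1 removes the influence of sampling density, so the embedding
reflects geometry only), row-normalize to a Markov matrix, and take its
leading eigenvectors as coordinates.  "Output-informed" means the distances
are measured between behavior vectors, so the coordinates parameterize the
model manifold — the set of attainable outputs — rather than parameter space.

Successive eigenvectors of a diffusion operator often re-parameterize
directions already captured (higher harmonics).  The parsimonious selection of
Dsilva et al. scores each eigenvector by how well it can be predicted from the
previously retained ones via leave-one-out local linear regression; a residual
near 1 marks a genuinely new direction.  The number of retained (nonharmonic)
eigenvectors is the intrinsic dimension estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "DiffusionMapModel",
    "choose_epsilon",
    "dmaps_fit",
    "parsimonious_select",
    "nystrom_extend",
    "intrinsic_dimension",
    "pca_explained",
]


def choose_epsilon(distances, rule: str = "median") -> float:
    """Kernel scale from a set of pairwise distances.

    ``median``: the median squared pairwise distance — scale-equivariant
    (scaling the data by c scales eps by c^2) and adequate for the compact,
    roughly uniform ensembles produced by box perturbation.  ``plateau``:
    the log-log kernel-sum rule — pick the eps maximizing the slope of
    log(sum_ij exp(-d_ij^2/eps)) vs log(eps), i.e. the center of the scaling
    region between the kernel's diagonal and saturated regimes.
    """
    d = np.asarray(distances, dtype=float).ravel()
    d = d[d > 0] if np.any(d > 0) else d
    if d.size == 0:
        raise ValueError("need at least one positive distance")
    if rule == "median":
        return float(np.median(d) ** 2)
    if rule == "plateau":
        d2 = d**2
        # reconstruct n from the number of pairs so the kernel sum includes
        # the diagonal; S then runs from n (tiny eps) to n^2 (huge eps) and
        # the slope of log S vs log eps peaks in the scaling region between
        n = int(round((1 + np.sqrt(1 + 8 * d2.size)) / 2))
        eps_grid = np.logspace(
            np.log10(np.percentile(d2, 1)) - 2, np.log10(d2.max()) + 2, 60
        )
        logS = np.array([np.log(n + 2 * np.sum(np.exp(-d2 / e))) for e in eps_grid])
        slopes = np.gradient(logS, np.log(eps_grid))
        return float(eps_grid[np.argmax(slopes)])
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class DiffusionMapModel:
    """Fitted diffusion map: kernel metadata plus eigenpairs on training data.

    ``eigenvectors[:, 0]`` is the constant vector with eigenvalue 1;
    nontrivial coordinates start at column 1.  ``retained`` holds indices
    (into the nontrivial columns, 1-based like the eigenvalue ordering) chosen
    by parsimonious selection; ``residuals`` the corresponding scores.
    """

    points: np.ndarray
    epsilon: float
    alpha: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    q: np.ndarray  # raw kernel row sums (density estimates) on training data
    d: np.ndarray  # row sums after alpha-normalization
    retained: list = field(default_factory=list)
    residuals: np.ndarray | None = None

    @property
    def coords(self) -> np.ndarray:
        """Retained nonharmonic coordinates (n x k), in retained order."""
        if not self.retained:
            raise ValueError("no retained indices; run parsimonious_select first")
        return self.eigenvectors[:, self.retained]

    def save(self, path) -> None:
        import json
        from pathlib import Path

        import pandas as pd

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "epsilon": self.epsilon,
            "alpha": self.alpha,
            "retained": list(map(int, self.retained)),
            "residuals": None if self.residuals is None else self.residuals.tolist(),
        }
        (path / "kernel.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(self.points).to_csv(path / "points.csv", index=False)
        pd.DataFrame(self.eigenvectors).to_csv(path / "eigenvectors.csv", index=False)
        pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "q": np.resize(self.q, self.eigenvalues.shape)}
        ).to_csv(path / "eigenvalues.csv", index=False)
        pd.DataFrame({"q": self.q, "d": self.d}).to_csv(path / "density.csv", index=False)

    @classmethod
    def load(cls, path) -> "DiffusionMapModel":
        import json
        from pathlib import Path

        import pandas as pd

        path = Path(path)
        meta = json.loads((path / "kernel.json").read_text())
        dens = pd.read_csv(path / "density.csv")
        return cls(
            points=pd.read_csv(path / "points.csv").to_numpy(dtype=float),
            epsilon=meta["epsilon"],
            alpha=meta["alpha"],
            eigenvalues=pd.read_csv(path / "eigenvalues.csv")["eigenvalue"].to_numpy(),
            eigenvectors=pd.read_csv(path / "eigenvectors.csv").to_numpy(dtype=float),
            q=dens["q"].to_numpy(),
            d=dens["d"].to_numpy(),
            retained=list(meta["retained"]),
            residuals=None if meta["residuals"] is None else np.asarray(meta["residuals"]),
        )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first entry of magnitude > tol positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * max(np.abs(col).max(), 1e-300))[0]
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def dmaps_fit(X, epsilon: float | None = None, alpha: float = 1.0, m: int = 20) -> DiffusionMapModel:
    """Fit a diffusion map with m nontrivial eigenpairs.

    The Markov operator is diagonalized through its symmetric conjugate
    D^{-1/2} W~ D^{-1/2}, so the eigenproblem is well conditioned and the
    eigenvalues are real.  Eigenvectors are rescaled so the trivial one is
    identically 1 and signs are fixed (first significant entry positive),
    making the fit deterministic on identical input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n points x ambient dimension)")
    n = X.shape[0]
    if n < m + 1:
        raise ValueError(f"need at least m+1={m + 1} points, got {n}")
    dists = squareform(pdist(X))
    if epsilon is None:
        epsilon = choose_epsilon(dists[np.triu_indices(n, 1)])
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    W = np.exp(-(dists**2) / epsilon)
    q = W.sum(axis=1)
    if np.any(q - 1.0 < 1e-14):
        raise ValueError(
            "kernel is numerically diagonal at this epsilon; increase epsilon"
        )
    if alpha != 0:
        W = W / np.outer(q**alpha, q**alpha)
    d = W.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    A = W * np.outer(d_inv_sqrt, d_inv_sqrt)
    # symmetric conjugate of the Markov matrix: same spectrum
    eigvals, eigvecs = eigh(A, subset_by_index=(n - (m + 1), n - 1))
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], -1.0, 1.0)
    phi = eigvecs[:, order] * d_inv_sqrt[:, None]
    phi = phi / phi[:, [0]].mean(axis=0)  # trivial eigenvector -> constant 1
    phi[:, 0] = 1.0
    phi = np.column_stack([phi[:, 0], _fix_signs(phi[:, 1:])])
    return DiffusionMapModel(
        points=X,
        epsilon=float(epsilon),
        alpha=float(alpha),
        eigenvalues=eigvals,
        eigenvectors=phi,
        q=q,
        d=d,
    )


class _LocalLinear:
    """Leave-one-out Gaussian-weighted local linear regression on fixed predictors.

    The normal matrices depend only on the predictors and the bandwidth, so
    they are factored once and reused for every response vector.
    """

    def __init__(self, P: np.ndarray, bandwidth: float):
        n = P.shape[0]
        W = np.exp(-squareform(pdist(P)) ** 2 / bandwidth**2)
        np.fill_diagonal(W, 0.0)  # leave-one-out
        self.Xd = np.column_stack([np.ones(n), P])
        p1 = self.Xd.shape[1]
        A = np.empty((n, p1, p1))
        for a in range(p1):
            for b in range(a, p1):
                Aab = W @ (self.Xd[:, a] * self.Xd[:, b])
                A[:, a, b] = Aab
                A[:, b, a] = Aab
        A += 1e-10 * np.eye(p1)
        self.A = A
        self.W = W

    def residual(self, y: np.ndarray) -> float:
        """Normalized LOO residual ||y - yhat|| / ||y - mean(y)||, capped at 1."""
        c = self.W @ (self.Xd * y[:, None])
        beta = np.linalg.solve(self.A, c[..., None])[..., 0]
        yhat = np.einsum("ij,ij->i", self.Xd, beta)
        denom = np.sum((y - y.mean()) ** 2)
        if denom == 0:
            return 0.0
        return min(1.0, float(np.sqrt(np.sum((y - yhat) ** 2) / denom)))

    def remaining_fraction(self, Y: np.ndarray) -> float:
        """Fraction of (centered) multivariate variance the fit leaves unexplained."""
        p1 = self.Xd.shape[1]
        C = np.empty((Y.shape[0], p1, Y.shape[1]))
        for a in range(p1):
            C[:, a, :] = self.W @ (self.Xd[:, a : a + 1] * Y)
        beta = np.linalg.solve(self.A, C)
        Yhat = np.einsum("ij,ijd->id", self.Xd, beta)
        Yc = Y - Y.mean(axis=0)
        return float(np.linalg.norm(Y - Yhat) / np.linalg.norm(Yc))


def _multi_bandwidth(P, scales):
    med = np.median(pdist(P))
    return [med / s for s in scales if med / s > 0]


def parsimonious_select(
    eigenvectors: np.ndarray,
    X: np.ndarray | None = None,
    threshold: float = 0.5,
    smooth_threshold: float = 0.15,
    resolution: float = 1e-3,
    bandwidth_scales=(1.5, 3.0, 6.0, 12.0),
):
    """Nonharmonic eigenvector selection by leave-one-out local linear fits.

    ``eigenvectors`` are the nontrivial columns (the constant one excluded);
    the first is always retained (residual 1 by convention).  Each candidate
    is regressed, Gaussian-weighted with the evaluation point left out, on
    the coordinates retained so far; the residual is minimized over a small
    sweep of bandwidths (a harmonic of the retained coordinates becomes
    predictable once the bandwidth resolves its wavelength, while a genuinely
    new direction stays unpredictable at every bandwidth).  Candidates with
    residual above ``threshold`` open a new direction.

    When the ambient points ``X`` are supplied, two safeguards are added.
    First, a candidate must itself be a smooth function over the data: its
    LOO residual against the ambient coordinates must fall below
    ``smooth_threshold``.  A genuinely resolvable coordinate of the data is
    locally (almost) a linear function of the ambient position and scores
    near 0; eigenvectors that oscillate within directions thinner than the
    regression can resolve at the sampled density score far higher and are
    never counted.  This makes the smoothness test the effective resolution
    cut of the dimension count.  Second, if the retained coordinates already
    explain the ambient data to within ``resolution`` (relative remaining
    variance), counting stops — a guard against degenerate inputs.

    Returns ``(retained_column_indices, residuals)``.
    """
    V = np.asarray(eigenvectors, dtype=float)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ValueError("need at least 2 nontrivial eigenvectors")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    n, m = V.shape
    residuals = np.zeros(m)
    residuals[0] = 1.0
    retained = [0]
    ambient_fits = None
    if X is not None:
        Xs = np.asarray(X, dtype=float)
        ambient_fits = [_LocalLinear(Xs, bw) for bw in _multi_bandwidth(Xs, bandwidth_scales)]
    pred_fits = None
    for k in range(1, m):
        if pred_fits is None:
            P = V[:, retained]
            pred_fits = [_LocalLinear(P, bw) for bw in _multi_bandwidth(P, bandwidth_scales)]
            if X is not None:
                # least-biased (most local) estimate of what is left to explain
                if min(f.remaining_fraction(Xs) for f in pred_fits) < resolution:
                    break
        y = V[:, k]
        residuals[k] = min(f.residual(y) for f in pred_fits)
        if residuals[k] > threshold:
            if ambient_fits is not None and min(f.residual(y) for f in ambient_fits) >= smooth_threshold:
                continue  # not a smooth function over the data: skip, don't count
            retained.append(k)
            pred_fits = None
    return retained, residuals


def nystrom_extend(model: DiffusionMapModel, x_new, *, outlier_factor: float = 3.0) -> np.ndarray:
    """Out-of-sample eigenvector values via the Nystrom extension.

    Reconstructs the normalized kernel row of each new point against the
    training set and divides by the eigenvalues; at a training point this
    reproduces the stored eigenvector entries.  Points farther from the
    training cloud than ``outlier_factor`` kernel scales trigger an
    extrapolation warning (the extension decays to zero out there).
    """
    X_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    dists = cdist(X_new, model.points)
    if np.any(dists.min(axis=1) ** 2 > outlier_factor * model.epsilon):
        warnings.warn(
            "Nystrom extension evaluated far outside the training cloud; "
            "values are extrapolated and unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    W = np.exp(-(dists**2) / model.epsilon)
    if model.alpha != 0:
        q_new = W.sum(axis=1)
        W = W / np.outer(q_new**model.alpha, model.q**model.alpha)
    P = W / W.sum(axis=1, keepdims=True)
    lam = model.eigenvalues.copy()
    lam[np.abs(lam) < 1e-15] = np.inf  # dead modes extend to zero
    return (P @ model.eigenvectors) / lam


def intrinsic_dimension(
    dataset,
    mode: str = "output-informed",
    *,
    epsilon: float | None = None,
    epsilon_scale: float = 20.0,
    alpha: float = 1.0,
    m: int = 25,
    threshold: float = 0.5,
    smooth_threshold: float = 0.15,
):
    """Count effective dimensions of an ensemble via DMaps + parsimonious selection.

    ``output-informed`` builds the kernel on behavior vectors (model-manifold
    dimension = number of effective parameters); ``parameter-space`` builds it
    on standardized parameter vectors (e.g. the manifold of equivalent
    optima, whose dimension counts the redundant combinations).

    Unless ``epsilon`` is given explicitly, the kernel scale is set to
    ``epsilon_scale`` times the median-rule value.  The wide-kernel regime is
    deliberate: for strongly anisotropic manifolds the eigenvalue ordering
    then ranks one eigenvector per independent direction ahead of the
    harmonics of the dominant directions (for a Gaussian cloud the
    eigenfunctions are Hermite polynomials of the principal axes, and
    widening the kernel favors first-order modes of thin axes over
    high-order modes of the leading one), so a small number of computed
    eigenpairs suffices to see every direction thicker than ``resolution``.

    Returns ``(dimension, fitted model)`` with retained indices populated.
    """
    if mode == "output-informed":
        X = dataset.behaviors
    elif mode == "parameter-space":
        X = dataset.parameters
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if epsilon is None:
        epsilon = epsilon_scale * choose_epsilon(pdist(X))
    m = min(m, X.shape[0] - 2)
    model = dmaps_fit(X, epsilon=epsilon, alpha=alpha, m=m)
    retained, residuals = parsimonious_select(
        model.eigenvectors[:, 1:], X, threshold=threshold, smooth_threshold=smooth_threshold
    )
    model.retained = [r + 1 for r in retained]  # shift past the trivial column
    model.residuals = residuals
    return len(retained), model


def pca_explained(Y) -> np.ndarray:
    """Explained-variance ratios of the principal components of Y (descending)."""
    from sklearn.decomposition import PCA

    Y = np.asarray(Y, dtype=float)
    return PCA(n_components=min(Y.shape[0], Y.shape[1])).fit(Y).explained_variance_ratio_
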