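"""Geometric Harmonics interpolation and the Double-DMaps directed maps.

Geometric Harmonics (GH) extends a function known on scattered samples to new
points: diagonalize the Gaussian kernel matrix on the training inputs, keep
the eigenpairs above a spectral cutoff, project the function on that basis,
and evaluate out-of-sample through the kernel columns.  It is simultaneously
a (truncated-basis) smoother on the training set and a Nystrom-type
out-of-sample extension.

"Double DMaps" applies the same idea on a reduced manifold: a first diffusion
map supplies intrinsic coordinates phi for the data, a second diffusion map is
computed *on those coordinates*, and its eigenvectors serve as the basis for
functions of phi.  Composing with the first map's Nystrom extension gives
fully out-of-sample prediction: new ambient point -> phi -> function value.

The directed maps used in the analyses are built on top:

* ``BehaviorPredictor`` — effective parameters kappa -> output time series;
* ``EffectiveParameterEstimator`` — observed behavior -> kappa;
* ``jacobian_determinant`` — finite-difference Jacobian diagnostics for
  checking that a learned map phi -> kappa is locally invertible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist

from .dmaps import DiffusionMapModel, choose_epsilon, dmaps_fit, nystrom_extend, parsimonious_select

__all__ = [
    "HarmonicInterpolant",
    "DoubleDMapsInterpolant",
    "gh_fit",
    "double_dmaps_fit",
    "BehaviorPredictor",
    "EffectiveParameterEstimator",
    "jacobian_determinant",
    "OutOfManifoldError",
]


class OutOfManifoldError(ValueError):
    """A query point lies too far from the sampled manifold to be trusted."""


@dataclass
class HarmonicInterpolant:
    """Truncated kernel-eigenbasis interpolant (plain Geometric Harmonics)."""

    points: np.ndarray
    epsilon: float
    sigmas: np.ndarray  # retained kernel eigenvalues, descending
    psis: np.ndarray  # retained orthonormal eigenvectors (n x L)
    coeffs: np.ndarray  # <f, psi_l> per output component (L x d)

    @property
    def fitted_values(self) -> np.ndarray:
        """The projection of the training values on the retained span."""
        return self.psis @ self.coeffs

    def __call__(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        K = np.exp(-cdist(x_new, self.points) ** 2 / self.epsilon)
        return (K @ self.psis) / self.sigmas @ self.coeffs

    def refit(self, values: np.ndarray) -> "HarmonicInterpolant":
        """Fit new output values against the same basis (idempotent on its own output)."""
        F = np.asarray(values, dtype=float)
        if F.ndim == 1:
            F = F[:, None]
        return HarmonicInterpolant(
            self.points, self.epsilon, self.sigmas, self.psis, self.psis.T @ F
        )


def gh_fit(
    points: np.ndarray,
    values: np.ndarray,
    epsilon: float | None = None,
    delta: float = 1e-6,
    n_modes: int | None = None,
) -> HarmonicInterpolant:
    """Fit Geometric Harmonics to (points, values).

    ``epsilon`` defaults to 4x the median-rule scale: the extension kernel is
    deliberately wider than a DMaps kernel would be, because the basis must
    reach out-of-sample rather than resolve fine structure.  Eigenpairs with
    sigma_l >= delta * sigma_0 are retained (``delta`` bounds the norm
    amplification of the extension by 1/delta).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    F = np.asarray(values, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    n = X.shape[0]
    if F.shape[0] != n:
        raise ValueError("points and values must have the same number of rows")
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1); delta >= 1 would retain nothing")
    if epsilon is None:
        epsilon = 4.0 * choose_epsilon(pdist(X))
    K = np.exp(-cdist(X, X) ** 2 / epsilon)
    if n_modes is None:
        n_modes = min(n, 500)
    sig, psi = eigh(K, subset_by_index=(n - n_modes, n - 1))
    order = np.argsort(sig)[::-1]
    sig, psi = sig[order], psi[:, order]
    keep = sig >= delta * sig[0]
    sig, psi = sig[keep], psi[:, keep]
    return HarmonicInterpolant(X, float(epsilon), sig, psi, psi.T @ F)


@dataclass
class DoubleDMapsInterpolant:
    """GH over the retained coordinates of a diffusion map.

    The basis functions are the eigenvectors of a second diffusion map fitted
    on the first map's retained coordinates; projection uses the stationary
    measure of the second map (under which its eigenvectors are orthogonal).
    Evaluation at a new coordinate point goes through the second map's
    Nystrom extension.
    """

    first: DiffusionMapModel
    second: DiffusionMapModel
    n_modes: int
    coeffs: np.ndarray  # (n_modes x d) projection coefficients

    def eval_coords(self, phi_new: np.ndarray) -> np.ndarray:
        """Evaluate at points given directly in the first map's coordinate space."""
        ext = nystrom_extend(self.second, np.atleast_2d(phi_new))
        return ext[:, : self.n_modes] @ self.coeffs

    def __call__(self, x_new: np.ndarray) -> np.ndarray:
        """Evaluate at new ambient points of the first diffusion map."""
        phi_new = nystrom_extend(self.first, np.atleast_2d(x_new))[:, self.first.retained]
        return self.eval_coords(phi_new)

    @property
    def fitted_values(self) -> np.ndarray:
        return self.second.eigenvectors[:, : self.n_modes] @ self.coeffs


def double_dmaps_fit(
    model: DiffusionMapModel,
    values: np.ndarray,
    epsilon2: float | None = None,
    m2: int = 300,
    delta: float = 1e-8,
) -> DoubleDMapsInterpolant:
    """Fit a Double-DMaps interpolant for functions of the model's coordinates.

    A second diffusion map is computed on ``model.coords``; its eigenvectors
    (orthogonal under its stationary measure) form the approximation basis.
    ``m2`` eigenpairs are computed and those with eigenvalue above ``delta``
    times the leading nontrivial one are used.
    """
    F = np.asarray(values, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    phi = model.coords
    n = phi.shape[0]
    if F.shape[0] != n:
        raise ValueError("values must have one row per training point")
    m2 = min(m2, n - 2)
    second = dmaps_fit(phi, epsilon=epsilon2, m=m2)
    lam = second.eigenvalues
    n_modes = int(np.sum(lam >= delta * max(lam[1], 1e-300)))
    n_modes = max(n_modes, 2)
    V = second.eigenvectors[:, :n_modes]
    w = second.d / second.d.sum()  # stationary measure of the second map
    gram = (w[:, None] * V * V).sum(axis=0)
    coeffs = (V * w[:, None]).T @ F / gram[:, None]
    return DoubleDMapsInterpolant(model, second, n_modes, coeffs)


def _box_guard(X_train: np.ndarray, x: np.ndarray, margin: float = 0.05, what: str = "query"):
    lo, hi = X_train.min(axis=0), X_train.max(axis=0)
    span = hi - lo
    if np.any(x < lo - margin * span) or np.any(x > hi + margin * span):
        warnings.warn(
            f"{what} outside the sampled range; prediction is an extrapolation",
            RuntimeWarning,
            stacklevel=3,
        )


class BehaviorPredictor:
    """Map new effective-parameter values to the predicted output time series.

    Fit on an ensemble of (effective parameters, behaviors): a diffusion map
    over the parameter triplets supplies intrinsic coordinates, and every
    element of the behavior vector is interpolated over them with Double
    DMaps.  Prediction for a new triplet goes through the Nystrom extension.
    """

    def __init__(self, dataset, *, epsilon_scale: float = 4.0, m2: int = 300, delta: float = 1e-8):
        self.dataset = dataset
        K = dataset.parameters
        eps = epsilon_scale * choose_epsilon(pdist(K))
        model = dmaps_fit(K, epsilon=eps, m=12)
        retained, residuals = parsimonious_select(model.eigenvectors[:, 1:], K)
        model.retained = [r + 1 for r in retained]
        model.residuals = residuals
        self.model = model
        self.interp = double_dmaps_fit(model, dataset.behaviors, m2=m2, delta=delta)

    def predict(self, kappa_new) -> np.ndarray:
        k = np.atleast_2d(
            kappa_new.to_array() if hasattr(kappa_new, "to_array") else np.asarray(kappa_new, float)
        )
        _box_guard(self.dataset.parameters, k, what="effective-parameter triplet")
        out = self.interp(k)
        return out[0] if out.shape[0] == 1 and np.ndim(kappa_new) <= 1 else out


class EffectiveParameterEstimator:
    """Estimate effective parameters from a newly observed behavior vector.

    The inverse direction: a diffusion map over behaviors (the model
    manifold), with the effective parameters interpolated over its retained
    coordinates.  A new behavior is projected onto the manifold by Nystrom;
    behaviors far off the manifold raise :class:`OutOfManifoldError`.
    """

    def __init__(
        self,
        dataset,
        values: np.ndarray | None = None,
        *,
        epsilon_scale: float = 20.0,
        m: int = 25,
        m2: int = 300,
        delta: float = 1e-8,
        max_kernel_scales: float = 3.0,
    ):
        self.dataset = dataset
        B = dataset.behaviors
        # wide-kernel regime, as in intrinsic-dimension counting, so the
        # retained coordinates span every resolvable manifold direction
        eps = epsilon_scale * choose_epsilon(pdist(B))
        model = dmaps_fit(B, epsilon=eps, m=m)
        retained, residuals = parsimonious_select(model.eigenvectors[:, 1:], B)
        model.retained = [r + 1 for r in retained]
        model.residuals = residuals
        self.model = model
        self.max_kernel_scales = max_kernel_scales
        if values is None:
            values = dataset.parameters
        self.interp = double_dmaps_fit(model, values, m2=m2, delta=delta)

    def estimate(self, behavior_new) -> np.ndarray:
        b = np.atleast_2d(np.asarray(behavior_new, dtype=float))
        d2 = cdist(b, self.model.points).min(axis=1) ** 2
        if np.any(d2 > self.max_kernel_scales * self.model.epsilon):
            raise OutOfManifoldError(
                "behavior lies too far from the sampled model manifold "
                f"(min squared distance {d2.max():.3g} > "
                f"{self.max_kernel_scales:g} x epsilon {self.model.epsilon:.3g})"
            )
        out = self.interp(b)
        return out[0] if out.shape[0] == 1 and np.ndim(behavior_new) == 1 else out


def jacobian_determinant(f, points: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """det of the central-finite-difference Jacobian of ``f`` at each point.

    The step per coordinate is ``rel_step`` times that coordinate's range
    over ``points``.  ``f`` must map (n, d) -> (n, d).
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = P.shape
    span = P.max(axis=0) - P.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    steps = rel_step * span
    cols = []
    for j in range(d):
        e = np.zeros(d)
        e[j] = steps[j]
        cols.append((np.asarray(f(P + e)) - np.asarray(f(P - e))) / (2 * steps[j]))
    J = np.stack(cols, axis=-1)  # (n, d_out, d_in)
    if J.shape[1] != J.shape[2]:
        raise ValueError("jacobian_determinant requires a square map")
    return np.linalg.det(J)
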