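"""Y-shaped conformal autoencoder: disentangling what matters from what does not.

The network reparameterizes the original parameters p into latent coordinates
nu of the same dimension, split into an *effective* block (the first ``n_eff``
entries) and a *redundant* block (the rest):

* an encoder maps p -> nu;
* a decoder maps nu -> p (reconstruction);
* a behavior estimator maps ONLY the effective block to the observed output
  vector, so the redundant coordinates are architecturally unable to
  influence predicted behavior;
* optionally, a parameter estimator maps behaviors back to the effective
  latent (the package's primary behavior -> nu_1 route is the Double-DMaps
  map, see :func:`estimate_nu1_from_behavior`).

The loss adds a conformality penalty: the input-gradients of the latent
coordinates must be mutually orthogonal, <d nu_i, d nu_j> = 0 for i != j.
With behavior forced through the effective block alone, orthogonality pushes
the remaining coordinates to span the level sets of constant behavior:
varying them moves the parameters without changing the output.  ``n_eff``
must be known in advance — it is the model-manifold dimension counted by
:func:`effparam.dmaps.intrinsic_dimension`.

Training is on standardized parameters and behaviors, so orthogonality is
imposed in the standardized parameter metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, Adam, Tensor

__all__ = [
    "ConformalLatent",
    "CAEConfig",
    "CAEModel",
    "train_cae",
    "encode",
    "decode",
    "orthogonality_score",
    "trace_level_set",
    "estimate_nu1_from_behavior",
]


@dataclass(frozen=True)
class ConformalLatent:
    """A latent vector partitioned into effective and redundant blocks."""

    nu: np.ndarray
    n_eff: int

    @property
    def effective(self) -> np.ndarray:
        return self.nu[..., : self.n_eff]

    @property
    def redundant(self) -> np.ndarray:
        return self.nu[..., self.n_eff :]


@dataclass
class CAEConfig:
    """Training configuration; weights are (reconstruction, behavior, orthogonality)."""

    hidden: tuple = (32, 32, 32, 32)
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 2000
    weights: tuple = (1.0, 1.0, 1.0)
    val_fraction: float = 0.1
    patience: int = 200
    lr_decay: float = 0.1
    lr_milestones: tuple = (0.6, 0.85)
    with_param_estimator: bool = False


@dataclass
class CAEModel:
    encoder: MLP
    decoder: MLP
    behavior_net: MLP
    n_eff: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    seed: int
    config: CAEConfig
    report: dict = field(default_factory=dict)
    param_net: MLP | None = None

    def encode(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        z = (np.atleast_2d(p) - self.x_mean) / self.x_std
        nu = self.encoder.numpy_call(z)
        return nu[0] if single else nu

    def decode(self, nu) -> np.ndarray:
        nu = np.asarray(nu, dtype=float)
        single = nu.ndim == 1
        nu2 = np.atleast_2d(nu)
        if nu2.shape[1] != self.encoder.sizes[-1]:
            raise ValueError("latent dimension mismatch")
        lo, hi = self.report["nu_min"], self.report["nu_max"]
        if np.any(nu2 < lo - 0.25 * (hi - lo)) or np.any(nu2 > hi + 0.25 * (hi - lo)):
            warnings.warn(
                "latent point outside the range seen in training; decoded "
                "parameters are an extrapolation",
                RuntimeWarning,
                stacklevel=2,
            )
        x = self.decoder.numpy_call(nu2) * self.x_std + self.x_mean
        return x[0] if single else x

    def predict_behavior(self, p) -> np.ndarray:
        nu = np.atleast_2d(self.encode(p))
        y = self.behavior_net.numpy_call(nu[:, : self.n_eff]) * self.y_std + self.y_mean
        return y[0] if np.asarray(p).ndim == 1 else y


def train_cae(dataset, n_eff: int, config: CAEConfig | None = None, seed: int = 0) -> CAEModel:
    """Train the conformal autoencoder on a (parameters, behaviors) ensemble.

    The total loss is

        w1 * reconstruction MSE + w2 * behavior MSE
            + w3 * mean over pairs i<j of <d nu_i, d nu_j>^2,

    all in standardized units; the behavior estimator receives only the
    effective latent block.  Returns the model with a training report
    holding the final value of each loss term and the latent ranges.
    """
    cfg = config or CAEConfig()
    X = np.asarray(dataset.parameters, dtype=float)
    Y = np.asarray(dataset.behaviors, dtype=float)
    n, P = X.shape
    if not 1 <= n_eff < P:
        raise ValueError(f"n_eff must lie in [1, {P - 1}] (got {n_eff})")
    x_mean, x_std = X.mean(0), np.where(X.std(0) > 0, X.std(0), 1.0)
    y_mean, y_std = Y.mean(0), np.where(Y.std(0) > 0, Y.std(0), 1.0)
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_mean) / y_std
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(cfg.val_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr, Xval, Yval = Xs[tr_idx], Ys[tr_idx], Xs[val_idx], Ys[val_idx]

    encoder = MLP((P, *cfg.hidden, P), seed=seed)
    decoder = MLP((P, *cfg.hidden, P), seed=seed + 1)
    behavior = MLP((n_eff, *cfg.hidden, Y.shape[1]), seed=seed + 2)
    param_net = (
        MLP((Y.shape[1], *cfg.hidden, n_eff), seed=seed + 3)
        if cfg.with_param_estimator
        else None
    )
    params = encoder.params + decoder.params + behavior.params
    if param_net is not None:
        params = params + param_net.params
    opt = Adam(params, lr=cfg.lr)
    w1, w2, w3 = cfg.weights
    pairs = [(i, j) for i in range(P) for j in range(i + 1, P)]

    def batch_terms(xb_np, yb_np):
        xb, yb = Tensor(xb_np), Tensor(yb_np)
        nu, J = encoder.forward_with_jacobian(xb)
        recon = ((decoder(nu) - xb) ** 2).mean()
        beh = ((behavior(nu[:, :n_eff]) - yb) ** 2).mean()
        # squared cosine between latent input-gradients: scale-free, so flat
        # regions cannot hide residual non-orthogonality
        sq_norms = [(J[:, i, :] * J[:, i, :]).sum(axis=1) for i in range(P)]
        orth = Tensor(0.0)
        for i, j in pairs:
            dots = (J[:, i, :] * J[:, j, :]).sum(axis=1)
            orth = orth + (dots**2 * (sq_norms[i] * sq_norms[j] + 1e-12) ** -1).mean()
        orth = orth * (1.0 / len(pairs))
        extra = Tensor(0.0)
        if param_net is not None:
            extra = ((param_net(yb) - nu[:, :n_eff]) ** 2).mean()
        return recon, beh, orth, extra

    best_val, best_state, since_best = np.inf, None, 0
    milestones = {int(m * cfg.epochs) for m in cfg.lr_milestones}
    for epoch in range(cfg.epochs):
        if epoch in milestones:
            opt.lr *= cfg.lr_decay
        order = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            recon, beh, orth, extra = batch_terms(Xtr[idx], Ytr[idx])
            loss = w1 * recon + w2 * beh + w3 * orth + extra
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: recon={recon.data:.3g} "
                    f"behavior={beh.data:.3g} orthogonality={orth.data:.3g}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
        recon, beh, orth, extra = batch_terms(Xval, Yval)
        val = float((w1 * recon + w2 * beh + w3 * orth + extra).data)
        if val < best_val:
            best_val, since_best = val, 0
            best_state = [p.data.copy() for p in params]
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    for p, s in zip(params, best_state):
        p.data = s.copy()

    model = CAEModel(
        encoder=encoder,
        decoder=decoder,
        behavior_net=behavior,
        n_eff=n_eff,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        seed=seed,
        config=cfg,
        param_net=param_net,
    )
    recon, beh, orth, extra = batch_terms(Xs, Ys)
    nu_all = model.encode(X)
    model.report = {
        "seed": seed,
        "epochs_run": epoch + 1,
        "reconstruction_mse": float(recon.data),
        "behavior_mse": float(beh.data),
        "orthogonality": float(orth.data),
        "val_loss": best_val,
        "nu_min": nu_all.min(0),
        "nu_max": nu_all.max(0),
    }
    return model


def encode(model: CAEModel, p) -> ConformalLatent:
    return ConformalLatent(nu=model.encode(p), n_eff=model.n_eff)


def decode(model: CAEModel, nu) -> np.ndarray:
    nu = nu.nu if isinstance(nu, ConformalLatent) else nu
    return model.decode(nu)


def orthogonality_score(model: CAEModel, points) -> float:
    """Mean |cos angle| between input-gradients of latent pairs over points.

    0 means perfectly conformal latent coordinates; by convention the score
    of a single-latent model (no pairs) is 0.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    Z = (X - model.x_mean) / model.x_std
    J = model.encoder.numpy_jacobian(Z)  # (n, P, P)
    P = J.shape[1]
    if P < 2:
        return 0.0
    norms = np.linalg.norm(J, axis=2)
    scores = []
    for i in range(P):
        for j in range(i + 1, P):
            dots = np.abs((J[:, i, :] * J[:, j, :]).sum(axis=1))
            scores.append(dots / (norms[:, i] * norms[:, j] + 1e-300))
    return float(np.mean(scores))


def trace_level_set(model: CAEModel, nu_eff_fixed, grid, simulate=None):
    """Decode a grid over the redundant block at fixed effective coordinates.

    ``grid`` is an (m, n_red) array of redundant-latent values (build it e.g.
    from the observed latent range).  Returns a dict with the decoded
    parameter vectors, and — when ``simulate`` (parameter row -> behavior
    vector) is given — the simulated behaviors, the maximum relative behavior
    deviation from the grid's center point (level-set quality), and the
    relative parameter spread along the surface.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    n_red = model.encoder.sizes[-1] - model.n_eff
    if grid.shape[1] != n_red:
        raise ValueError(f"grid must have {n_red} columns (the redundant block)")
    nu_eff = np.atleast_1d(np.asarray(nu_eff_fixed, dtype=float))
    nus = np.column_stack([np.tile(nu_eff, (grid.shape[0], 1)), grid])
    params = model.decode(nus)
    out = {"nu": nus, "parameters": params}
    if simulate is not None:
        behaviors = np.asarray([simulate(row) for row in params])
        center = behaviors[len(behaviors) // 2]
        dev = np.abs(behaviors - center) / np.maximum(np.abs(center), 1e-300)
        spread = (params.max(0) - params.min(0)) / np.abs(params.mean(0))
        out.update(
            behaviors=behaviors,
            max_behavior_deviation=float(dev.max()),
            parameter_spread=spread,
        )
    return out


def estimate_nu1_from_behavior(model: CAEModel, dataset, behavior_new, **kwargs):
    """Estimate the effective latent block for new behaviors via Double DMaps.

    Fits a behavior -> nu_eff map on the training ensemble (diffusion map
    over behaviors, effective latents interpolated over its coordinates) and
    evaluates it at the new behavior(s).  Behaviors far off the sampled
    manifold raise :class:`effparam.harmonics.OutOfManifoldError`.
    """
    from .harmonics import EffectiveParameterEstimator

    nu_eff = model.encode(dataset.parameters)[:, : model.n_eff]
    est = EffectiveParameterEstimator(dataset, nu_eff, **kwargs)
    return est.estimate(behavior_new)
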