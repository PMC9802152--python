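"""Ensemble generation: every dataset the downstream analyses consume.

The datasets are paired matrices (parameters, behaviors): transient ensembles
obtained by jiggling rate constants around a base point, an "equivalent
optima" ensemble of least-squares refits of a reference transient, ensembles
over the reduced model's effective-parameter space, time-delay / parameter
pairs for jointly-smooth-function extraction, and an analytic two-parameter
toy with a known effective (p1*p2) and redundant (p1^2 - p2^2) combination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from . import kinetics
from .kinetics import (
    CARICATURE_OBSERVATION_TIMES,
    CARICATURE_REFERENCE_IC,
    DEFAULT_OBSERVATION_TIMES,
    MSP_BASE,
    MSP_REFERENCE_IC,
    CaricatureParameters,
    EffectiveParameters,
    MSPParameters,
    MSPState,
)

__all__ = [
    "EnsembleDataset",
    "sample_parameters",
    "build_transient_dataset",
    "build_caricature_dataset",
    "build_optimization_dataset",
    "sample_kappa_dataset",
    "build_jsf_pair",
    "analytic_toy_dataset",
]


@dataclass
class EnsembleDataset:
    """Paired (parameters, behaviors) matrices plus provenance metadata.

    Row i of ``behaviors`` is the simulated output of row i of ``parameters``.
    """

    parameters: np.ndarray
    behaviors: np.ndarray
    parameter_names: tuple
    times: np.ndarray
    observable: str
    base: np.ndarray | None = None
    fraction: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=float)
        self.behaviors = np.asarray(self.behaviors, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.parameters.ndim != 2 or self.behaviors.ndim != 2:
            raise ValueError("parameters and behaviors must be 2-D matrices")
        if self.parameters.shape[0] != self.behaviors.shape[0]:
            raise ValueError("parameters and behaviors must have the same row count")
        if self.parameters.shape[0] == 0:
            raise ValueError("dataset must contain at least one sample")
        if not (np.isfinite(self.parameters).all() and np.isfinite(self.behaviors).all()):
            raise ValueError("dataset contains non-finite entries")

    @property
    def n(self) -> int:
        return self.parameters.shape[0]

    def split(self, n_train: int):
        """Deterministic head/tail split into (train, test) datasets."""
        if not 0 < n_train < self.n:
            raise ValueError(f"n_train must be in (0, {self.n})")
        parts = []
        for sl in (slice(0, n_train), slice(n_train, None)):
            parts.append(
                EnsembleDataset(
                    parameters=self.parameters[sl],
                    behaviors=self.behaviors[sl],
                    parameter_names=self.parameter_names,
                    times=self.times,
                    observable=self.observable,
                    base=self.base,
                    fraction=self.fraction,
                    seed=self.seed,
                    meta=dict(self.meta),
                )
            )
        return tuple(parts)

    def to_dir(self, path) -> None:
        import pandas as pd

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.parameters, columns=list(self.parameter_names)).to_csv(
            path / "parameters.csv", index=False
        )
        cols = [f"{self.observable}_t{t:g}" for t in self.times] if self.times.size == self.behaviors.shape[1] else [f"y{j}" for j in range(self.behaviors.shape[1])]
        pd.DataFrame(self.behaviors, columns=cols).to_csv(path / "behaviors.csv", index=False)
        meta = {
            "parameter_names": list(self.parameter_names),
            "times": self.times.tolist(),
            "observable": self.observable,
            "base": None if self.base is None else np.asarray(self.base).tolist(),
            "fraction": self.fraction,
            "seed": self.seed,
            "meta": self.meta,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path) -> "EnsembleDataset":
        import pandas as pd

        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        try:
            params = pd.read_csv(path / "parameters.csv").to_numpy(dtype=float)
            behav = pd.read_csv(path / "behaviors.csv").to_numpy(dtype=float)
        except ValueError as exc:  # non-numeric cells etc.
            raise ValueError(f"malformed ensemble CSV under {path}: {exc}") from exc
        return cls(
            parameters=params,
            behaviors=behav,
            parameter_names=tuple(meta["parameter_names"]),
            times=np.asarray(meta["times"], dtype=float),
            observable=meta["observable"],
            base=None if meta["base"] is None else np.asarray(meta["base"], dtype=float),
            fraction=meta["fraction"],
            seed=meta["seed"],
            meta=meta.get("meta", {}),
        )


def sample_parameters(base, fraction: float, n: int, seed: int) -> np.ndarray:
    """Uniform box sampling: each column on [base*(1-f), base*(1+f)].

    ``fraction=0`` degenerates to n copies of the base point (useful for
    smoke checks); otherwise 0 < fraction < 1 keeps all rates positive.
    """
    base = np.asarray(base.to_array() if hasattr(base, "to_array") else base, dtype=float)
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lo = base * (1.0 - fraction)
    hi = base * (1.0 + fraction)
    return rng.uniform(lo, hi, size=(n, base.size))


def _simulate_rows(params, simulate_one):
    rows = [simulate_one(p) for p in params]
    return np.asarray(rows, dtype=float)


def build_transient_dataset(
    params: np.ndarray,
    ic: MSPState = MSP_REFERENCE_IC,
    times=DEFAULT_OBSERVATION_TIMES,
    observable: str = "S2",
    *,
    base=None,
    fraction=None,
    seed=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> EnsembleDataset:
    """Simulate the full MSP model for each parameter row; record one species.

    The default observable is the product concentration [S2] on the 10-point
    grid t in {2, 4, ..., 20}, i.e. a 10-D behavior vector per parameter
    vector.  Any other species can be recorded instead — by the delay-embedding
    argument, the intrinsic dimensionality found downstream is the same.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))

    def one(row):
        traj = kinetics.simulate_msp(
            MSPParameters.from_array(row), ic, times, rtol=rtol, atol=atol
        )
        return traj[observable]

    return EnsembleDataset(
        parameters=params,
        behaviors=_simulate_rows(params, one),
        parameter_names=MSPParameters.names,
        times=np.asarray(times, dtype=float),
        observable=observable,
        base=None if base is None else np.asarray(base.to_array() if hasattr(base, "to_array") else base),
        fraction=fraction,
        seed=seed,
    )


def build_caricature_dataset(
    params: np.ndarray,
    ic=CARICATURE_REFERENCE_IC,
    times=CARICATURE_OBSERVATION_TIMES,
    observable: str = "S1",
    *,
    base=None,
    fraction=None,
    seed=None,
) -> EnsembleDataset:
    """Simulate the single-site caricature for each (kf, kr, kcat) row."""
    params = np.atleast_2d(np.asarray(params, dtype=float))

    def one(row):
        traj = kinetics.simulate_caricature(CaricatureParameters.from_array(row), ic, times)
        return traj[observable]

    return EnsembleDataset(
        parameters=params,
        behaviors=_simulate_rows(params, one),
        parameter_names=CaricatureParameters.names,
        times=np.asarray(times, dtype=float),
        observable=observable,
        base=None if base is None else np.asarray(base.to_array() if hasattr(base, "to_array") else base),
        fraction=fraction,
        seed=seed,
    )


def build_optimization_dataset(
    reference: np.ndarray | None = None,
    n_fits: int = 1000,
    bounds_decades: float = 3.0,
    seed: int = 0,
    *,
    base: MSPParameters = MSP_BASE,
    ic: MSPState = MSP_REFERENCE_IC,
    times=DEFAULT_OBSERVATION_TIMES,
    threshold: float = 1e-4,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    max_nfev: int = 400,
    starts: np.ndarray | None = None,
) -> EnsembleDataset:
    """Refit the reference transient from random starts: the equivalent optima.

    All six rate constants are refit by nonlinear least squares against the
    reference [S2] transient.  Starting guesses are drawn log10-uniformly
    within ``10**(+-bounds_decades)`` of the base rates and the fit runs in
    log10-parameter space (trust-region reflective, box bounds; positivity is
    automatic in log space).  A fit is accepted when its relative RMS residual
    ||r|| / ||reference|| falls below ``threshold``; by construction every
    accepted parameter vector reproduces the reference behavior to within that
    threshold, so the accepted set samples the behavior level set through the
    base point.
    """
    times = np.asarray(times, dtype=float)
    if reference is None:
        reference = kinetics.simulate_msp(base, ic, times)["S2"]
    reference = np.asarray(reference, dtype=float)
    ref_norm = float(np.linalg.norm(reference))
    if ref_norm == 0:
        raise ValueError("reference behavior is identically zero")
    log_base = np.log10(base.to_array())
    if starts is None:
        rng = np.random.default_rng(seed)
        starts = rng.uniform(
            log_base - bounds_decades, log_base + bounds_decades, size=(n_fits, 6)
        )
    else:
        starts = np.atleast_2d(np.log10(np.asarray(starts, dtype=float)))

    def residual(logp):
        try:
            traj = kinetics.simulate_msp(
                MSPParameters.from_array(10.0 ** logp), ic, times, rtol=rtol, atol=atol
            )
        except kinetics.IntegrationError:
            return np.full(times.size, 1e6)
        return traj["S2"] - reference

    accepted, behaviors, residuals = [], [], []
    for x0 in starts:
        sol = least_squares(
            residual,
            x0,
            bounds=(log_base - bounds_decades, log_base + bounds_decades),
            method="trf",
            x_scale="jac",
            max_nfev=max_nfev,
        )
        if np.linalg.norm(sol.fun) / ref_norm > 2 * threshold:
            continue
        # confirm the fit at the simulator's full accuracy before accepting
        p_fit = 10.0**sol.x
        b = kinetics.simulate_msp(MSPParameters.from_array(p_fit), ic, times)["S2"]
        rel = np.linalg.norm(b - reference) / ref_norm
        if rel <= threshold:
            accepted.append(p_fit)
            behaviors.append(b)
            residuals.append(rel)
    if not accepted:
        raise RuntimeError(
            "no least-squares fit reached the acceptance threshold; "
            "loosen `threshold` or increase `n_fits`"
        )

    ds = EnsembleDataset(
        parameters=np.asarray(accepted),
        behaviors=np.asarray(behaviors),
        parameter_names=MSPParameters.names,
        times=times,
        observable="S2",
        base=base.to_array(),
        fraction=None,
        seed=seed,
        meta={
            "kind": "optimization",
            "n_fits": n_fits,
            "n_accepted": len(residuals),
            "bounds_decades": bounds_decades,
            "threshold": threshold,
            "residuals": [float(r) for r in residuals],
        },
    )
    return ds


def sample_kappa_dataset(
    kappa_nominal: EffectiveParameters,
    fraction: float = 0.2,
    n: int = 5000,
    seed: int = 0,
    *,
    ic=(5.0, 0.0, 0.0),
    times=DEFAULT_OBSERVATION_TIMES,
) -> EnsembleDataset:
    """Ensemble over reduced-model effective parameters (closed-form behaviors)."""
    triplets = sample_parameters(kappa_nominal.to_array(), fraction, n, seed)

    def one(row):
        return kinetics.simulate_reduced(EffectiveParameters.from_array(row), ic, times)["S2"]

    return EnsembleDataset(
        parameters=triplets,
        behaviors=_simulate_rows(triplets, one),
        parameter_names=EffectiveParameters.names,
        times=np.asarray(times, dtype=float),
        observable="S2",
        base=kappa_nominal.to_array(),
        fraction=fraction,
        seed=seed,
    )


def build_jsf_pair(
    params: np.ndarray,
    ic=CARICATURE_REFERENCE_IC,
    t_step: float = 0.5,
    species=("S0", "S1", "ES0", "E"),
    n_delays: int = 20,
    *,
    noise_half: bool = False,
    seed: int = 0,
):
    """Time-delay observation / parameter matrix pair for JSF extraction.

    For each caricature parameter row, ``n_delays`` consecutive measurements
    (spacing ``t_step``) of each listed species are concatenated into one
    observation row x1; x2 holds the raw parameter rows.  With the default four
    species and 20 delays, x1 has width 80.  ``noise_half=True`` replaces the
    second half of each species' delay block with uniform noise spanning the
    measurement range of that block — a robustness stressor: those columns
    carry no information about the parameters.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    if n_delays < 1:
        raise ValueError("n_delays must be >= 1")
    times = t_step * np.arange(1, n_delays + 1)
    order = {"S0": 0, "E": 1, "S1": 2, "ES0": 3}
    idx = [order[s] for s in species]
    rows = []
    for row in params:
        traj = kinetics.simulate_caricature(CaricatureParameters.from_array(row), ic, times)
        rows.append(traj.states[:, idx].T.ravel())  # species-major blocks of delays
    X1 = np.asarray(rows)
    if noise_half:
        rng = np.random.default_rng(seed)
        half = n_delays // 2
        for s in range(len(species)):
            cols = slice(s * n_delays + (n_delays - half), (s + 1) * n_delays)
            block = X1[:, cols]
            X1[:, cols] = rng.uniform(block.min(), block.max(), size=block.shape)
    return X1, params.copy()


def analytic_toy_dataset(n: int = 2000, seed: int = 0, low: float = 0.5, high: float = 1.5):
    """Analytic nonidentifiable toy: output f = exp(-p1 p2 / 2).

    The output depends on the two parameters only through their product
    phi = p1 p2 (the effective combination); psi = p1^2 - p2^2 parameterizes
    the level sets of phi and is everywhere conformal to it (grad phi is
    orthogonal to grad psi at every point).  Sampling is uniform on
    [low, high]^2, a window that keeps f well away from its saturation at 1.

    Returns ``(params, f, phi, psi)`` with ``params`` of shape (n, 2) and the
    rest of shape (n,).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    params = rng.uniform(low, high, size=(n, 2))
    phi = params[:, 0] * params[:, 1]
    psi = params[:, 0] ** 2 - params[:, 1] ** 2
    f = np.exp(-phi / 2.0)
    return params, f, phi, psi
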