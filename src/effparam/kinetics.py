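"""Mass-action forward models for the phosphorylation testbeds.

Three mechanisms are built in:

* the dual (multisite) phosphorylation (MSP) mechanism in which a kinase E
  converts substrate S0 -> S1 -> S2 through the complexes ES0 and ES1,
  governed by six rate constants;
* its quasi-steady-state (QSSA) reduction, a linear three-state model in the
  effective parameters (kappa1, kappa2, pi);
* a single-site caricature S0 + E <-> ES0 -> S1 + E with three rate constants,
  whose QSSA collapses everything onto the single effective rate k_eff.

All simulators integrate the exact mass-action ODEs with a stiff solver
(rates span five orders of magnitude at the nominal operating points); the
reduced model is solved in closed form since it is linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MSPParameters",
    "MSPState",
    "EffectiveParameters",
    "CaricatureParameters",
    "Trajectory",
    "IntegrationError",
    "MSP_BASE",
    "CARICATURE_BASE_K1",
    "CARICATURE_BASE_K2",
    "KAPPA_NOMINAL",
    "MSP_REFERENCE_IC",
    "CARICATURE_REFERENCE_IC",
    "DEFAULT_OBSERVATION_TIMES",
    "CARICATURE_OBSERVATION_TIMES",
    "msp_rhs",
    "simulate_msp",
    "effective_parameters",
    "simulate_reduced",
    "simulate_caricature",
    "k_eff",
    "qssa_validity",
]


class IntegrationError(RuntimeError):
    """Raised when the stiff ODE solver fails; carries solver diagnostics."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class MSPParameters:
    """The six rate constants of the dual-phosphorylation mechanism.

    ``kf*`` are binding rates (per concentration per time); ``kr*`` and
    ``kcat*`` are unbinding/catalytic rates (per time).
    """

    kf1: float
    kr1: float
    kcat1: float
    kf2: float
    kr2: float
    kcat2: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))

    # canonical storage order used throughout the package
    names = ("kf1", "kr1", "kcat1", "kf2", "kr2", "kcat2")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "MSPParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError(f"expected 6 rate constants, got shape {values.shape}")
        return cls(**dict(zip(cls.names, values)))

    @classmethod
    def from_printed_vector(cls, values, assignment: str = "consistent") -> "MSPParameters":
        """Interpret a vector printed in the order (kf1, kr1, kcat1, ?, ?, kcat2).

        The nominal operating point is published with its 4th and 5th entries
        ambiguous between kf2 and kr2.  ``assignment="consistent"`` reads them
        as (kr2, kf2), the reading under which the published effective
        parameters (kappa1, kappa2, pi) = (0.467, 0.232, 0.362) are reproduced;
        ``assignment="printed"`` follows the literal label order (kf2, kr2).
        """
        v = np.asarray(values, dtype=float)
        if v.shape != (6,):
            raise ValueError("expected a vector of 6 entries")
        if assignment == "consistent":
            return cls(kf1=v[0], kr1=v[1], kcat1=v[2], kr2=v[3], kf2=v[4], kcat2=v[5])
        if assignment == "printed":
            return cls(kf1=v[0], kr1=v[1], kcat1=v[2], kf2=v[3], kr2=v[4], kcat2=v[5])
        raise ValueError(f"unknown assignment {assignment!r}")


#: Nominal MSP operating point, in the regime where the QSSA reduction holds.
MSP_BASE = MSPParameters.from_printed_vector([0.71, 19, 6700, 9200, 0.97, 5200])


@dataclass(frozen=True)
class MSPState:
    """Concentrations of the six MSP species."""

    E: float
    S0: float
    S1: float = 0.0
    S2: float = 0.0
    ES0: float = 0.0
    ES1: float = 0.0

    names = ("E", "S0", "S1", "S2", "ES0", "ES1")

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"concentration {f.name} must be nonnegative, got {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names], dtype=float)

    @property
    def E_tot(self) -> float:
        return self.E + self.ES0 + self.ES1

    @property
    def S_tot(self) -> float:
        return self.S0 + self.S1 + self.S2 + self.ES0 + self.ES1


#: Reference initial condition: substrate 5, enzyme 0.66, nothing else present.
MSP_REFERENCE_IC = MSPState(E=0.66, S0=5.0)

#: The product concentration [S2] is observed at t in {2, 4, ..., 20}.
DEFAULT_OBSERVATION_TIMES = np.arange(2.0, 21.0, 2.0)

#: Caricature outputs are recorded every 2 time units for five points.
CARICATURE_OBSERVATION_TIMES = np.arange(2.0, 11.0, 2.0)


@dataclass(frozen=True)
class EffectiveParameters:
    """QSSA effective parameters of the MSP model.

    kappa1 = [E] kf1 kcat1 / (kr1 + kcat1) is the effective rate of the first
    phosphorylation, kappa2 the analogous rate of the second, and
    pi = kcat2 / (kr2 + kcat2) the processivity: the probability that an ES1
    complex converts to product rather than releasing S1.  pi < 1 strictly
    whenever kr2 > 0.
    """

    kappa1: float
    kappa2: float
    pi: float

    names = ("kappa1", "kappa2", "pi")

    def __post_init__(self) -> None:
        _require_positive("kappa1", self.kappa1)
        _require_positive("kappa2", self.kappa2)
        if not (0 < self.pi < 1):
            raise ValueError(f"pi must lie strictly in (0, 1), got {self.pi!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.kappa1, self.kappa2, self.pi], dtype=float)

    @classmethod
    def from_array(cls, values) -> "EffectiveParameters":
        v = np.asarray(values, dtype=float)
        return cls(kappa1=v[0], kappa2=v[1], pi=v[2])


#: Effective parameters at the nominal MSP operating point (3 d.p.: 0.467, 0.231, 0.361).
def _kappa_nominal() -> EffectiveParameters:
    return effective_parameters(MSP_BASE, MSP_REFERENCE_IC.E)


@dataclass(frozen=True)
class CaricatureParameters:
    """Rate constants of the single-site mechanism S0 + E <-> ES0 -> S1 + E."""

    kf: float
    kr: float
    kcat: float

    names = ("kf", "kr", "kcat")

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))

    def to_array(self) -> np.ndarray:
        return np.array([self.kf, self.kr, self.kcat], dtype=float)

    @classmethod
    def from_array(cls, values) -> "CaricatureParameters":
        v = np.asarray(values, dtype=float)
        return cls(kf=v[0], kr=v[1], kcat=v[2])


CARICATURE_BASE_K1 = CaricatureParameters(kf=0.71, kr=19, kcat=6700)
CARICATURE_BASE_K2 = CaricatureParameters(kf=0.97, kr=7000, kcat=10000)

#: Reference caricature initial condition ([S0], [E], [S1], [ES0]).
CARICATURE_REFERENCE_IC = (5.0, 0.66, 0.0, 0.0)


@dataclass
class Trajectory:
    """A solved trajectory: output times by species concentrations."""

    times: np.ndarray
    states: np.ndarray
    species: tuple

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D array")
        if self.states.shape != (self.times.size, len(self.species)):
            raise ValueError("states must have shape (n_times, n_species)")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=list(self.species)).assign(time=self.times)[
            ["time", *self.species]
        ]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MSP full model
# ---------------------------------------------------------------------------

def msp_rhs(state, p: MSPParameters) -> np.ndarray:
    """Mass-action time derivatives for the MSP mechanism.

    State order is (E, S0, S1, S2, ES0, ES1).  The enzyme and substrate
    conservation sums of the returned derivatives vanish exactly.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (6,):
        raise ValueError("state must have 6 entries (E, S0, S1, S2, ES0, ES1)")
    if np.any(state < 0):
        raise ValueError("concentrations must be nonnegative")
    E, S0, S1, S2, ES0, ES1 = state
    bind1 = p.kf1 * E * S0
    bind2 = p.kf2 * E * S1
    dS0 = -bind1 + p.kr1 * ES0
    dES0 = bind1 - (p.kr1 + p.kcat1) * ES0
    dES1 = p.kcat1 * ES0 + bind2 - (p.kr2 + p.kcat2) * ES1
    dS1 = p.kr2 * ES1 - bind2
    dS2 = p.kcat2 * ES1
    dE = -dES0 - dES1
    return np.array([dE, dS0, dS1, dS2, dES0, dES1])


def _msp_rhs_raw(t, y, kf1, kr1, kcat1, kf2, kr2, kcat2):
    E, S0, S1, S2, ES0, ES1 = y
    bind1 = kf1 * E * S0
    bind2 = kf2 * E * S1
    dES0 = bind1 - (kr1 + kcat1) * ES0
    dES1 = kcat1 * ES0 + bind2 - (kr2 + kcat2) * ES1
    return (
        -dES0 - dES1,
        -bind1 + kr1 * ES0,
        kr2 * ES1 - bind2,
        kcat2 * ES1,
        dES0,
        dES1,
    )


def _msp_jac(t, y, kf1, kr1, kcat1, kf2, kr2, kcat2):
    E, S0, S1, S2, ES0, ES1 = y
    J = np.zeros((6, 6))
    # rows: E, S0, S1, S2, ES0, ES1; columns: same order
    # d(ES0)'/d. and d(ES1)'/d. first, then compose E' = -(ES0)' - (ES1)'
    dES0 = np.array([kf1 * S0, kf1 * E, 0.0, 0.0, -(kr1 + kcat1), 0.0])
    dES1 = np.array([kf2 * S1, 0.0, kf2 * E, 0.0, kcat1, -(kr2 + kcat2)])
    J[4] = dES0
    J[5] = dES1
    J[0] = -dES0 - dES1
    J[1] = np.array([-kf1 * S0, -kf1 * E, 0.0, 0.0, kr1, 0.0])
    J[2] = np.array([-kf2 * S1, 0.0, -kf2 * E, 0.0, 0.0, kr2])
    J[3] = np.array([0.0, 0.0, 0.0, 0.0, 0.0, kcat2])
    return J


def _integrate(fun, jac, y0, times, args, species, rtol, atol, method):
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a nonempty strictly increasing 1-D array")
    if times[0] < 0:
        raise ValueError("times must start at a nonnegative value")
    t0 = 0.0 if times[0] > 0 else times[0]
    sol = solve_ivp(
        fun,
        (t0, times[-1]),
        y0,
        method=method,
        t_eval=times,
        args=args,
        jac=jac,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"stiff integration failed: {sol.message} (method={method}, rtol={rtol})"
        )
    states = np.clip(sol.y.T, 0.0, None)  # clip solver-level negative round-off
    return Trajectory(times=times, states=states, species=species)


def simulate_msp(
    p: MSPParameters,
    ic: MSPState = MSP_REFERENCE_IC,
    times=DEFAULT_OBSERVATION_TIMES,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full MSP mass-action model and report the listed times."""
    y0 = ic.to_array()  # (E, S0, S1, S2, ES0, ES1)
    return _integrate(
        _msp_rhs_raw,
        _msp_jac,
        y0,
        times,
        (p.kf1, p.kr1, p.kcat1, p.kf2, p.kr2, p.kcat2),
        MSPState.names,
        rtol,
        atol,
        method,
    )


def effective_parameters(p: MSPParameters, E_conc: float) -> EffectiveParameters:
    """QSSA effective parameters (kappa1, kappa2, pi) at enzyme concentration [E]."""
    _require_positive("E_conc", E_conc)
    return EffectiveParameters(
        kappa1=E_conc * p.kf1 * p.kcat1 / (p.kr1 + p.kcat1),
        kappa2=E_conc * p.kf2 * p.kcat2 / (p.kr2 + p.kcat2),
        pi=p.kcat2 / (p.kr2 + p.kcat2),
    )


KAPPA_NOMINAL = _kappa_nominal()


# ---------------------------------------------------------------------------
# Reduced (QSSA) model — linear, solved in closed form
# ---------------------------------------------------------------------------

def simulate_reduced(k: EffectiveParameters, ic=(5.0, 0.0, 0.0), times=DEFAULT_OBSERVATION_TIMES) -> Trajectory:
    """Closed-form solution of the linear three-state QSSA model.

    dS0/dt = -kappa1 S0
    dS1/dt = (1 - pi) kappa1 S0 - kappa2 S1
    dS2/dt = pi kappa1 S0 + kappa2 S1

    The total S0 + S1 + S2 is conserved exactly, so S2 is recovered from the
    conservation law.  The confluent case kappa1 ~ kappa2 uses the limit
    (exp(-k1 t) - exp(-k2 t))/(k2 - k1) -> t exp(-k1 t).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and nonnegative")
    S00, S10, S20 = (float(v) for v in ic)
    if min(S00, S10, S20) < 0:
        raise ValueError("initial concentrations must be nonnegative")
    k1, k2, pi = k.kappa1, k.kappa2, k.pi
    e1 = np.exp(-k1 * times)
    e2 = np.exp(-k2 * times)
    if abs(k2 - k1) > 1e-9 * (k1 + k2):
        transfer = (e1 - e2) / (k2 - k1)
    else:
        transfer = times * e1
    S0 = S00 * e1
    S1 = S10 * e2 + (1.0 - pi) * k1 * S00 * transfer
    S2 = (S00 + S10 + S20) - S0 - S1
    states = np.column_stack([S0, S1, S2])
    return Trajectory(times=times, states=states, species=("S0", "S1", "S2"))


# ---------------------------------------------------------------------------
# Single-site caricature
# ---------------------------------------------------------------------------

def _car_rhs_raw(t, y, kf, kr, kcat):
    S0, E, S1, C = y
    bind = kf * E * S0
    dC = bind - (kr + kcat) * C
    return (-bind + kr * C, -dC, kcat * C, dC)


def _car_jac(t, y, kf, kr, kcat):
    S0, E, S1, C = y
    dC = np.array([kf * E, kf * S0, 0.0, -(kr + kcat)])
    return np.array(
        [
            [-kf * E, -kf * S0, 0.0, kr],
            -dC,
            [0.0, 0.0, 0.0, kcat],
            dC,
        ]
    )


def simulate_caricature(
    k: CaricatureParameters,
    ic=CARICATURE_REFERENCE_IC,
    times=CARICATURE_OBSERVATION_TIMES,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the single-site mechanism; state order (S0, E, S1, ES0)."""
    y0 = np.asarray(ic, dtype=float)
    if y0.shape != (4,) or np.any(y0 < 0):
        raise ValueError("ic must be 4 nonnegative concentrations (S0, E, S1, ES0)")
    return _integrate(
        _car_rhs_raw,
        _car_jac,
        y0,
        times,
        (k.kf, k.kr, k.kcat),
        ("S0", "E", "S1", "ES0"),
        rtol,
        atol,
        method,
    )


def k_eff(k: CaricatureParameters, E_tot: float) -> float:
    """QSSA effective rate of the caricature: E_tot kf kcat / (kr + kcat)."""
    _require_positive("E_tot", E_tot)
    return E_tot * k.kf * k.kcat / (k.kr + k.kcat)


def qssa_validity(p: MSPParameters, S_tot: float, threshold: float = 0.1, *, as_printed: bool = False):
    """Check the QSSA smallness conditions for the MSP model.

    Returns ``(ratio1, ratio2, ok1, ok2)`` where ratio_i = S_tot / K_i and
    K_i is the relevant Michaelis-type constant of each binding step
    ((kr,i + kcat,i)/kf,i).  The approximation is considered valid when both
    ratios fall below ``threshold``.  ``as_printed=True`` evaluates the first
    constant as (kf,1 + kcat,1)/kf,1 instead — a variant that circulates in
    the literature but is dimensionally inconsistent for a binding step.
    """
    if S_tot < 0:
        raise ValueError("S_tot must be nonnegative")
    num1 = (p.kf1 + p.kcat1) if as_printed else (p.kr1 + p.kcat1)
    K1 = num1 / p.kf1
    K2 = (p.kr2 + p.kcat2) / p.kf2
    r1 = S_tot / K1
    r2 = S_tot / K2
    return r1, r2, bool(r1 < threshold), bool(r2 < threshold)
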