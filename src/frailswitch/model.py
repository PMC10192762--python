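"""Core ODE model: a mutually inhibitory IGF-1/IL-6 toggle coupled to
mobility-prevalence dynamics.

The state of a hypothetical individual is five-dimensional:

* ``IGF1`` (ng/ml) and ``IL6`` (pg/ml) form a double-negative feedback
  motif.  Each biomarker is produced at a constant rate, inhibited by a
  Hill-type function of the other (Hill coefficient 2 by default, the
  cooperativity required for bistability), and cleared linearly::

      dIGF1/dt = kp_IGF1 / (1 + ks_IL6 * IL6**n) - kd_IGF1 * IGF1
      dIL6/dt  = kp_IL6  / (1 + ks_IGF1 * IGF1**n) - kd_IL6 * IL6

* ``M`` (mobile), ``MD`` (mobility disability) and ``D`` (dead) are
  prevalence scores summing to one.  IL-6 drives loss of mobility,
  IGF-1 drives recovery, and mortality follows a Gompertz hazard
  ``k_mort * exp(k_longevity * t)``, amplified by ``k_extra`` for the
  disabled compartment::

      dM/dt  = -k_loss*IL6*M + k_gain*IGF1*MD - h(t)*M
      dMD/dt =  k_loss*IL6*M - k_gain*IGF1*MD - k_extra*h(t)*MD
      dD/dt  =  h(t)*(M + k_extra*MD)

  ``D`` is integrated from its own right-hand side (the negated sum of
  the other two), so the conservation ``M + MD + D = 1`` is a genuine
  test of the integrator rather than an identity imposed by
  substitution.

Time is measured in months throughout; IGF-1 in ng/ml (identically
mcg/L) and IL-6 in pg/ml.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

__all__ = [
    "BiomarkerParams",
    "OutcomeParams",
    "StateVector",
    "Trajectory",
    "SteadyState",
    "SimulationError",
    "biomarker_rhs",
    "outcome_rhs",
    "simulate",
    "simulate_biomarkers",
    "find_biomarker_steady_states",
    "stable_states",
    "integrate_to_steady_state",
    "classify_attractor",
    "closed_form_survival",
    "save_parameters",
    "load_parameters",
]

CONSERVATION_TOL = 1e-6
#: user-supplied states more negative than this are treated as errors,
#: anything smaller in magnitude is solver roundoff and clipped to zero
NEG_GUARD = 1e-7
#: cap on the Gompertz exponent, keeps the hazard finite long after extinction
_EXP_CAP = 500.0

_UNITS = {
    "kp_IGF1": "ng/ml/month",
    "ks_IL6": "(pg/ml)^-hill_n",
    "kd_IGF1": "1/month",
    "kp_IL6": "pg/ml/month",
    "ks_IGF1": "(ng/ml)^-hill_n",
    "kd_IL6": "1/month",
    "hill_n": "dimensionless",
    "k_loss": "1/(pg/ml)/month",
    "k_gain": "1/(ng/ml)/month",
    "k_mort": "1/month",
    "k_longevity": "1/month",
    "k_extra": "dimensionless",
}


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last successful time."""

    def __init__(self, message: str, last_t: float | None = None):
        super().__init__(message)
        self.last_t = last_t


@dataclass(frozen=True)
class BiomarkerParams:
    """Rate constants of the IGF-1/IL-6 mutual-inhibition subsystem."""

    kp_IGF1: float  # production, ng/ml per month
    ks_IL6: float   # inhibition of IGF-1 production by IL-6, (pg/ml)^-n
    kd_IGF1: float  # degradation, 1/month
    kp_IL6: float   # production, pg/ml per month
    ks_IGF1: float  # inhibition of IL-6 production by IGF-1, (ng/ml)^-n
    kd_IL6: float   # degradation, 1/month
    hill_n: int = 2

    def __post_init__(self):
        for name in ("kp_IGF1", "ks_IL6", "kd_IGF1", "kp_IL6", "ks_IGF1", "kd_IL6"):
            v = getattr(self, name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in ("kp_IGF1", "kd_IGF1", "kp_IL6", "kd_IL6"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be a positive integer")

    @property
    def igf1_max(self) -> float:
        """Uninhibited IGF-1 steady state kp/kd (the physiological ceiling)."""
        return self.kp_IGF1 / self.kd_IGF1

    @property
    def il6_max(self) -> float:
        return self.kp_IL6 / self.kd_IL6

    def to_dict(self) -> dict:
        return {
            "kp_IGF1": self.kp_IGF1, "ks_IL6": self.ks_IL6, "kd_IGF1": self.kd_IGF1,
            "kp_IL6": self.kp_IL6, "ks_IGF1": self.ks_IGF1, "kd_IL6": self.kd_IL6,
            "hill_n": self.hill_n,
        }


@dataclass(frozen=True)
class OutcomeParams:
    """Rate constants coupling biomarkers to the clinical compartments."""

    k_loss: float       # M -> MD per unit IL-6, 1/month
    k_gain: float       # MD -> M per unit IGF-1, 1/month
    k_mort: float       # baseline mortality, 1/month
    k_longevity: float  # exponential mortality acceleration, 1/month
    k_extra: float = 2.5

    def __post_init__(self):
        # zero rates are legal (frozen-dynamics limits used as test oracles);
        # negative rates are not
        for name in ("k_loss", "k_gain", "k_mort", "k_longevity", "k_extra"):
            v = getattr(self, name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.k_extra < 1.0:
            raise ValueError("k_extra must be >= 1 (disabled hazard is amplified)")

    def hazard(self, t):
        """Gompertz mortality hazard of the mobile compartment at time t."""
        return self.k_mort * np.exp(np.minimum(self.k_longevity * np.asarray(t), _EXP_CAP))

    def to_dict(self) -> dict:
        return {
            "k_loss": self.k_loss, "k_gain": self.k_gain, "k_mort": self.k_mort,
            "k_longevity": self.k_longevity, "k_extra": self.k_extra,
        }


@dataclass(frozen=True)
class StateVector:
    """Full model state at one time point."""

    t: float
    IGF1: float
    IL6: float
    M: float = 1.0
    MD: float = 0.0
    D: float = 0.0

    def validate(self, tol: float = CONSERVATION_TOL) -> None:
        if self.IGF1 < -NEG_GUARD or self.IL6 < -NEG_GUARD:
            raise ValueError(f"negative concentration in state at t={self.t}")
        for name in ("M", "MD", "D"):
            v = getattr(self, name)
            if v < -tol or v > 1.0 + tol:
                raise ValueError(f"{name}={v} outside [0, 1] at t={self.t}")
        if abs(self.M + self.MD + self.D - 1.0) > tol:
            raise ValueError(
                f"prevalence scores do not conserve: M+MD+D={self.M + self.MD + self.D}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.IGF1, self.IL6, self.M, self.MD, self.D])


def _check_concentrations(igf1: float, il6: float) -> tuple[float, float]:
    if igf1 < -NEG_GUARD or il6 < -NEG_GUARD:
        raise ValueError(f"negative concentration: IGF1={igf1}, IL6={il6}")
    return max(igf1, 0.0), max(il6, 0.0)


def _biomarker_derivs(igf1, il6, p: BiomarkerParams):
    n = p.hill_n
    digf1 = p.kp_IGF1 / (1.0 + p.ks_IL6 * il6 ** n) - p.kd_IGF1 * igf1
    dil6 = p.kp_IL6 / (1.0 + p.ks_IGF1 * igf1 ** n) - p.kd_IL6 * il6
    return digf1, dil6


def biomarker_rhs(state: StateVector, p: BiomarkerParams) -> tuple[float, float]:
    """Time derivatives (dIGF1/dt, dIL6/dt) of the biomarker subsystem."""
    igf1, il6 = _check_concentrations(state.IGF1, state.IL6)
    return _biomarker_derivs(igf1, il6, p)


def outcome_rhs(
    state: StateVector, bp: BiomarkerParams, op: OutcomeParams
) -> tuple[float, float, float]:
    """Time derivatives (dM/dt, dMD/dt, dD/dt) of the prevalence scores.

    The death derivative is the negated sum of the other two, so the
    returned triple sums to zero identically.
    """
    igf1, il6 = _check_concentrations(state.IGF1, state.IL6)
    h = float(op.hazard(state.t))
    flow = op.k_loss * il6 * state.M - op.k_gain * igf1 * state.MD
    dm = -flow - h * state.M
    dmd = flow - op.k_extra * h * state.MD
    dd = -(dm + dmd)
    return dm, dmd, dd


def _full_rhs(t, y, bp: BiomarkerParams, op: OutcomeParams):
    igf1 = max(y[0], 0.0)  # solvers probe slightly negative values
    il6 = max(y[1], 0.0)
    m, md = y[2], y[3]
    digf1, dil6 = _biomarker_derivs(igf1, il6, bp)
    h = op.k_mort * math.exp(min(op.k_longevity * t, _EXP_CAP))
    flow = op.k_loss * il6 * m - op.k_gain * igf1 * md
    dm = -flow - h * m
    dmd = flow - op.k_extra * h * md
    return (digf1, dil6, dm, dmd, h * (m + op.k_extra * md))


@dataclass
class Trajectory:
    """A simulated time course on a strictly increasing grid."""

    t: np.ndarray
    IGF1: np.ndarray
    IL6: np.ndarray
    M: np.ndarray
    MD: np.ndarray
    D: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> StateVector:
        return StateVector(
            t=float(self.t[i]), IGF1=float(self.IGF1[i]), IL6=float(self.IL6[i]),
            M=float(self.M[i]), MD=float(self.MD[i]), D=float(self.D[i]),
        )

    @property
    def survival(self) -> np.ndarray:
        """Fraction still alive, M + MD."""
        return self.M + self.MD

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.M + self.MD + self.D - 1.0)))

    def validate(self, tol: float = CONSERVATION_TOL) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.conservation_error() > tol:
            raise ValueError(f"conservation drift {self.conservation_error():.3g} > {tol}")
        if np.any(np.diff(self.D) < -1e-9):
            raise ValueError("death prevalence must be non-decreasing")
        if min(self.IGF1.min(), self.IL6.min()) < -NEG_GUARD:
            raise ValueError("negative concentration in trajectory")
        for name in ("M", "MD", "D"):
            v = getattr(self, name)
            if v.min() < -tol or v.max() > 1.0 + tol:
                raise ValueError(f"{name} leaves [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.t,
                "IGF1_ng_ml": self.IGF1,
                "IL6_pg_ml": self.IL6,
                "M": self.M,
                "MD": self.MD,
                "D": self.D,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    initial: StateVector,
    bp: BiomarkerParams,
    op: OutcomeParams,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    validate: bool = True,
) -> Trajectory:
    """Integrate the full five-variable system on ``t_grid`` (months)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D sequence")
    initial.validate()
    y0 = initial.as_array()
    sol = solve_ivp(
        _full_rhs, (float(t_grid[0]), float(t_grid[-1])), y0,
        t_eval=t_grid, args=(bp, op), method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
        raise SimulationError(f"solver failed: {sol.message} (last good t={last})", last)
    traj = Trajectory(
        t=sol.t, IGF1=sol.y[0], IL6=sol.y[1], M=sol.y[2], MD=sol.y[3], D=sol.y[4],
        meta={"method": method, "rtol": rtol, "atol": atol,
              "nfev": int(sol.nfev), "initial": list(map(float, y0))},
    )
    if validate:
        traj.validate()
    return traj


def simulate_biomarkers(
    igf1_0: float,
    il6_0: float,
    p: BiomarkerParams,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the decoupled 2-D biomarker subsystem (fast path)."""
    igf1_0, il6_0 = _check_concentrations(igf1_0, il6_0)
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(t, y):
        return _biomarker_derivs(max(y[0], 0.0), max(y[1], 0.0), p)

    sol = solve_ivp(
        rhs, (float(t_grid[0]), float(t_grid[-1])), [igf1_0, il6_0],
        t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"biomarker solver failed: {sol.message}")
    return sol.y[0], sol.y[1]


# ---------------------------------------------------------------------------
# steady states


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the 2-D biomarker subsystem with stability label."""

    IGF1_star: float
    IL6_star: float
    stability: str  # "stable" | "saddle" | "unstable"
    eigenvalues: tuple[complex, complex]
    residual: float

    def as_array(self) -> np.ndarray:
        return np.array([self.IGF1_star, self.IL6_star])


def _jacobian(igf1: float, il6: float, p: BiomarkerParams) -> np.ndarray:
    n = p.hill_n
    d_igf_il6 = -p.kp_IGF1 * n * p.ks_IL6 * il6 ** (n - 1) / (1.0 + p.ks_IL6 * il6 ** n) ** 2
    d_il6_igf = -p.kp_IL6 * n * p.ks_IGF1 * igf1 ** (n - 1) / (1.0 + p.ks_IGF1 * igf1 ** n) ** 2
    return np.array([[-p.kd_IGF1, d_igf_il6], [d_il6_igf, -p.kd_IL6]])


def find_biomarker_steady_states(
    p: BiomarkerParams, n_scan: int = 4000
) -> list[SteadyState]:
    """All fixed points of the biomarker toggle, with stability labels.

    The 2-D fixed-point problem is reduced to one scalar equation by
    substituting the IL-6 nullcline into the IGF-1 nullcline; sign
    changes of the composed map are bracketed on a dense grid over
    [0, kp_IGF1/kd_IGF1], refined by Brent's method, and polished on the
    full 2-D system.  Stability follows from the analytic 2x2 Jacobian.
    """
    n = p.hill_n
    x_max = p.igf1_max
    y_max = p.il6_max

    def f2(x):  # IL-6 nullcline: IL6 as a function of IGF1
        return y_max / (1.0 + p.ks_IGF1 * x ** n)

    def g(x):  # composed scalar map, roots are fixed points
        return x_max / (1.0 + p.ks_IL6 * f2(x) ** n) - x

    xs = np.linspace(0.0, x_max, n_scan)
    gs = g(xs)
    roots: list[float] = []
    for i in range(len(xs) - 1):
        a, b = gs[i], gs[i + 1]
        if a == 0.0:
            roots.append(xs[i])
        elif a * b < 0.0:
            roots.append(brentq(g, xs[i], xs[i + 1], xtol=1e-13, rtol=1e-14))
    if gs[-1] == 0.0:
        roots.append(xs[-1])

    # de-duplicate brackets that straddle the same root
    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-7 * max(x_max, 1.0):
            dedup.append(r)

    states = []
    for x0 in dedup:
        y0 = f2(x0)
        sol, info, ier, _ = fsolve(
            lambda v: _biomarker_derivs(v[0], v[1], p), [x0, y0],
            full_output=True, xtol=1e-13,
        )
        x_star, y_star = (sol if ier == 1 else (x0, y0))
        res = float(np.hypot(*_biomarker_derivs(x_star, y_star, p)))
        jac = _jacobian(x_star, y_star, p)
        eig = np.linalg.eigvals(jac)
        det = float(np.linalg.det(jac))
        if det < 0:
            stability = "saddle"
        elif np.all(eig.real < 0):
            stability = "stable"
        else:
            stability = "unstable"
        states.append(
            SteadyState(float(x_star), float(y_star), stability,
                        (complex(eig[0]), complex(eig[1])), res)
        )
    states.sort(key=lambda s: s.IGF1_star)
    return states


def stable_states(states: list[SteadyState]) -> list[SteadyState]:
    """Stable fixed points sorted by IGF-1 (index 0 = low-IGF-1/frail side)."""
    return [s for s in states if s.stability == "stable"]


def integrate_to_steady_state(
    igf1_0: float,
    il6_0: float,
    p: BiomarkerParams,
    t_max: float = 1e4,
    chunk: float = 2000.0,
    rhs_tol: float = 1e-9,
) -> tuple[float, float, float, bool]:
    """Run the biomarker subsystem until the RHS vanishes (scaled per species).

    Returns (IGF1, IL6, time used, converged).  Convergence is declared
    when ``|rhs_i| <= rhs_tol * (1 + |y_i|)`` for both species, or at
    ``t_max`` months, whichever comes first.
    """
    igf1, il6 = _check_concentrations(igf1_0, il6_0)
    t = 0.0

    def rhs(t_, y):
        return _biomarker_derivs(max(y[0], 0.0), max(y[1], 0.0), p)

    while t < t_max:
        t_next = min(t + chunk, t_max)
        sol = solve_ivp(rhs, (t, t_next), [igf1, il6], method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise SimulationError(f"steady-state integration failed: {sol.message}", t)
        igf1, il6 = max(float(sol.y[0, -1]), 0.0), max(float(sol.y[1, -1]), 0.0)
        t = t_next
        dx, dy = _biomarker_derivs(igf1, il6, p)
        if abs(dx) <= rhs_tol * (1.0 + igf1) and abs(dy) <= rhs_tol * (1.0 + il6):
            return igf1, il6, t, True
    return igf1, il6, t, False


def classify_attractor(
    igf1: float,
    il6: float,
    attractors: Sequence[SteadyState],
    rel_tol: float = 0.01,
) -> int:
    """Index of the attractor matching (igf1, il6), or -1 if none within tol.

    Matching is by relative distance in log-concentration space, which is
    scale-free across the ~25 pg/ml vs ~400 ng/ml unit disparity.
    """
    eps = 1e-9
    best, best_d = -1, np.inf
    for i, s in enumerate(attractors):
        d = max(
            abs(math.log((igf1 + eps) / (s.IGF1_star + eps))),
            abs(math.log((il6 + eps) / (s.IL6_star + eps))),
        )
        if d < best_d:
            best, best_d = i, d
    # |log ratio| < rel_tol is ~1% relative difference per coordinate
    return best if best_d < rel_tol else -1


def closed_form_survival(t, k_mort: float, k_longevity: float, M0: float = 1.0):
    """Gompertz survival ``M0 * exp(-(k_mort/k_longevity)(e^{k_longevity t}-1))``.

    Test oracle for the mortality submodel (exact solution of dM/dt =
    -k_mort e^{k_longevity t} M).  At ``k_longevity == 0`` the simple
    exponential limit ``M0 exp(-k_mort t)`` is returned.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if k_longevity == 0.0:
        out = M0 * np.exp(-k_mort * t)
    else:
        out = M0 * np.exp(-(k_mort / k_longevity) * np.expm1(k_longevity * t))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# parameter round-trip


def save_parameters(path, bp: BiomarkerParams, op: OutcomeParams | None = None,
                    extra: dict | None = None) -> None:
    """Serialize parameters to JSON with explicit unit annotations."""
    doc: dict = {"biomarker": {}, "units": _UNITS}
    for k, v in bp.to_dict().items():
        doc["biomarker"][k] = v
    if op is not None:
        doc["outcome"] = op.to_dict()
    if extra:
        doc["meta"] = extra
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def load_parameters(path) -> tuple[BiomarkerParams, OutcomeParams | None]:
    with open(path) as fh:
        doc = json.load(fh)
    bp = BiomarkerParams(**doc["biomarker"])
    op = OutcomeParams(**doc["outcome"]) if "outcome" in doc else None
    return bp, op
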