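"""Cohort-level clinical outcomes: stratification, prevalence envelopes,
phenotype classification and death-state decomposition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    BiomarkerParams,
    OutcomeParams,
    SimulationError,
    StateVector,
    Trajectory,
    classify_attractor,
    integrate_to_steady_state,
    simulate,
)

__all__ = [
    "COHORT_LABELS",
    "CohortDefinition",
    "CohortEnvelope",
    "PhenotypeLabel",
    "stratify_population",
    "simulate_cohort",
    "classify_phenotype",
    "death_state_decomposition",
]

COHORT_LABELS = (
    "lowIGF_highIL6",
    "highIGF_highIL6",
    "lowIGF_lowIL6",
    "highIGF_lowIL6",
)


@dataclass(frozen=True)
class CohortDefinition:
    """One of the four IGF-1 x IL-6 strata."""

    label: str
    n: int
    igf1_range: tuple[float, float]
    il6_range: tuple[float, float]
    mean_igf1: float
    mean_il6: float
    baseline_disabled: float = 0.0

    def __post_init__(self):
        if self.label not in COHORT_LABELS:
            raise ValueError(f"unknown cohort label {self.label!r}")
        if self.n <= 0:
            raise ValueError("cohort size must be positive")


def stratify_population(
    individuals: pd.DataFrame,
    cutoff_igf1: float,
    cutoff_il6: float,
    igf1_bounds: tuple[float, float] | None = None,
    il6_bounds: tuple[float, float] | None = None,
) -> dict[str, CohortDefinition]:
    """Partition individuals into the four strata by biomarker cut-offs.

    Values exactly on a cut-off go to the lower-value stratum (documented
    convention).  The partition is exhaustive and disjoint; counts sum to
    the population size.  Strata may be empty when a cut-off falls beyond
    the data range; empty strata are simply absent from the result.
    """
    if cutoff_igf1 <= 0 or cutoff_il6 <= 0:
        raise ValueError("cut-offs must be positive")
    igf1 = individuals["IGF1"].to_numpy(float)
    il6 = individuals["IL6"].to_numpy(float)
    lo_igf = igf1 <= cutoff_igf1
    lo_il6 = il6 <= cutoff_il6
    if igf1_bounds is None:
        igf1_bounds = (float(igf1.min()), float(igf1.max()))
    if il6_bounds is None:
        il6_bounds = (float(il6.min()), float(il6.max()))
    masks = {
        "lowIGF_highIL6": lo_igf & ~lo_il6,
        "highIGF_highIL6": ~lo_igf & ~lo_il6,
        "lowIGF_lowIL6": lo_igf & lo_il6,
        "highIGF_lowIL6": ~lo_igf & lo_il6,
    }
    out: dict[str, CohortDefinition] = {}
    for label, mask in masks.items():
        n = int(mask.sum())
        if n == 0:
            continue
        igf_rng = (igf1_bounds[0], cutoff_igf1) if label.startswith("lowIGF") \
            else (cutoff_igf1, igf1_bounds[1])
        il6_rng = (il6_bounds[0], cutoff_il6) if label.endswith("lowIL6") \
            else (cutoff_il6, il6_bounds[1])
        out[label] = CohortDefinition(
            label=label, n=n, igf1_range=igf_rng, il6_range=il6_rng,
            mean_igf1=float(igf1[mask].mean()), mean_il6=float(il6[mask].mean()),
        )
    assert sum(c.n for c in out.values()) == len(individuals)
    return out


@dataclass
class CohortEnvelope:
    """Best-corner / mean / worst-corner mobility trajectories of a stratum.

    The best corner is the highest-IGF-1/lowest-IL-6 vertex of the
    stratum rectangle, the worst corner the opposite one.
    """

    cohort: CohortDefinition
    best: Trajectory
    mean: Trajectory
    worst: Trajectory

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.mean.t,
                "M_best": self.best.M,
                "M_mean": self.mean.M,
                "M_worst": self.worst.M,
            }
        )


def simulate_cohort(
    c: CohortDefinition,
    bp: BiomarkerParams,
    op: OutcomeParams,
    horizon: float = 360.0,
    n_points: int = 361,
) -> CohortEnvelope:
    """Simulate the stratum's corner and mean baselines over the horizon."""
    box_igf1 = (0.0, bp.igf1_max)
    box_il6 = (0.0, bp.il6_max)
    for igf1 in c.igf1_range:
        if not box_igf1[0] <= igf1 <= box_igf1[1]:
            raise ValueError(f"baseline IGF-1 {igf1} outside physiological box")
    for il6 in c.il6_range:
        if not box_il6[0] <= il6 <= box_il6[1]:
            raise ValueError(f"baseline IL-6 {il6} outside physiological box")
    t_grid = np.linspace(0.0, horizon, n_points)
    m0, md0 = 1.0 - c.baseline_disabled, c.baseline_disabled

    def run(igf1, il6):
        return simulate(
            StateVector(t=0.0, IGF1=igf1, IL6=il6, M=m0, MD=md0, D=0.0),
            bp, op, t_grid,
        )

    return CohortEnvelope(
        cohort=c,
        best=run(c.igf1_range[1], c.il6_range[0]),
        mean=run(c.mean_igf1, c.mean_il6),
        worst=run(c.igf1_range[0], c.il6_range[1]),
    )


@dataclass(frozen=True)
class PhenotypeLabel:
    """Two-phenotype call for a baseline biomarker pair."""

    label: str  # "mobile_resilient" | "frail_declining" | "boundary"
    basis: str  # "separatrix" or "simulation"
    distance: float  # signed IGF-1 distance to the critical curve
    corroborated: bool | None = None


def classify_phenotype(
    baseline: tuple[float, float],
    sep,  # SeparatrixCurve
    tol: float | None = None,
    bp: BiomarkerParams | None = None,
    corroborate: bool = False,
) -> PhenotypeLabel:
    """Side-of-separatrix phenotype call for a baseline (IGF-1, IL-6) pair.

    Points above the critical IGF-1 at their IL-6 level are
    mobile/resilient, below it frail/declining; points within ``tol``
    (default twice the separatrix bisection tolerance) receive the
    explicit boundary label.  With ``corroborate=True`` and biomarker
    parameters supplied, the call is checked by direct integration to
    the attractor.
    """
    igf1, il6 = baseline
    crit = sep.critical_igf1(il6)
    tol = 2.0 * sep.tol if tol is None else tol
    dist = igf1 - crit
    if abs(dist) <= tol:
        label = "boundary"
    elif dist > 0:
        label = "mobile_resilient"
    else:
        label = "frail_declining"
    corroborated = None
    if corroborate and bp is not None and label != "boundary":
        attr = sep.attractors
        x, y, _, conv = integrate_to_steady_state(igf1, il6, bp)
        idx = classify_attractor(x, y, attr) if conv else -1
        sim_label = {0: "frail_declining", 1: "mobile_resilient"}.get(idx, "unassigned")
        corroborated = sim_label == label
    return PhenotypeLabel(label=label, basis="separatrix", distance=float(dist),
                          corroborated=corroborated)


def death_state_decomposition(
    traj: Trajectory, bp: BiomarkerParams, op: OutcomeParams
) -> pd.DataFrame:
    """Cumulative death prevalence split by source compartment.

    Integrates the two death fluxes ``k_mort e^{k_longevity t} M`` and
    ``k_extra k_mort e^{k_longevity t} MD`` as additional state
    variables alongside the model, on the trajectory's own grid from its
    initial state, so the two cumulative integrals sum to D(t) to solver
    precision.
    """
    from .model import _full_rhs

    y0 = np.concatenate([traj.state(0).as_array(), [0.0, 0.0]])

    def rhs(t, y):
        d = _full_rhs(t, y[:5], bp, op)
        h = op.k_mort * np.exp(min(op.k_longevity * t, 500.0))
        return (*d, h * y[2], op.k_extra * h * y[3])

    sol = solve_ivp(rhs, (float(traj.t[0]), float(traj.t[-1])), y0,
                    t_eval=traj.t, method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise SimulationError(f"decomposition integration failed: {sol.message}")
    d_from_m, d_from_md = sol.y[5], sol.y[6]
    total = d_from_m + d_from_md
    return pd.DataFrame(
        {
            "time_months": traj.t,
            "death_from_M": d_from_m,
            "death_from_MD": d_from_md,
            "D": sol.y[4],
            "mobile_death_fraction": np.divide(
                d_from_m, total, out=np.zeros_like(total), where=total > 0
            ),
        }
    )
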