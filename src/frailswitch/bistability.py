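"""Phase-plane analyses of the biomarker toggle.

* :func:`scan_attractors` integrates a grid of initial conditions to
  steady state and labels each node by its attractor (the paper-style
  basin scan over 40-300 ng/ml IGF-1 x 1-10 pg/ml IL-6).
* :func:`find_separatrix` bisects along lines of fixed IL-6 for the
  critical initial IGF-1 separating the two basins.
* :func:`mobility_switch_curve` sweeps one biomarker's initial value and
  records the mobility prevalence score at several horizons; the
  critical threshold is the midpoint of the steepest transition of the
  curve normalized by its own maximum (the raw score decays with the
  Gompertz mortality at long horizons, so sharpness is meaningful only
  scale-free).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    BiomarkerParams,
    OutcomeParams,
    SimulationError,
    SteadyState,
    classify_attractor,
    find_biomarker_steady_states,
    integrate_to_steady_state,
    stable_states,
)
from . import constants as C

logger = logging.getLogger(__name__)

__all__ = [
    "InitialGrid",
    "PhaseDiagram",
    "SeparatrixCurve",
    "SwitchCurve",
    "scan_attractors",
    "find_separatrix",
    "mobility_switch_curve",
    "critical_threshold",
]


@dataclass(frozen=True)
class InitialGrid:
    """Rectangular grid of initial biomarker values."""

    igf1_range: tuple[float, float] = C.SCAN_IGF1_RANGE
    il6_range: tuple[float, float] = C.SCAN_IL6_RANGE
    n_igf1: int = 60
    n_il6: int = 60

    def __post_init__(self):
        for lo, hi in (self.igf1_range, self.il6_range):
            if not (0 < lo < hi):
                raise ValueError("ranges must be positive with min < max")
        if self.n_igf1 < 2 or self.n_il6 < 2:
            raise ValueError("grid needs at least 2 points per axis")

    @property
    def igf1_values(self) -> np.ndarray:
        return np.linspace(*self.igf1_range, self.n_igf1)

    @property
    def il6_values(self) -> np.ndarray:
        return np.linspace(*self.il6_range, self.n_il6)


@dataclass
class PhaseDiagram:
    """Attractor label per grid node (-1 = unassigned, flagged)."""

    igf1: np.ndarray
    il6: np.ndarray
    labels: np.ndarray        # shape (n_il6, n_igf1)
    conv_time: np.ndarray
    attractors: list[SteadyState]
    unassigned: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_labels(self) -> int:
        return len(np.unique(self.labels[self.labels >= 0]))

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(self.igf1, self.il6)
        return pd.DataFrame(
            {
                "IGF1_0": ii.ravel(),
                "IL6_0": jj.ravel(),
                "attractor": self.labels.ravel(),
                "conv_time_months": self.conv_time.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _label_initial(
    igf1_0: float, il6_0: float, p: BiomarkerParams,
    attractors: list[SteadyState], t_max: float = 1e4,
) -> tuple[int, float]:
    x, y, t, conv = integrate_to_steady_state(igf1_0, il6_0, p, t_max=t_max)
    if not conv:
        return -1, t
    return classify_attractor(x, y, attractors), t


def scan_attractors(
    grid: InitialGrid, bp: BiomarkerParams, t_max: float = 1e4
) -> PhaseDiagram:
    """Integrate every grid node to steady state and label its basin.

    Nodes that fail to converge by ``t_max`` or land outside the 1%
    matching tolerance of every stable state are labelled -1 and listed
    in ``unassigned`` — never silently dropped.
    """
    attractors = stable_states(find_biomarker_steady_states(bp))
    igf1_vals, il6_vals = grid.igf1_values, grid.il6_values
    labels = np.empty((grid.n_il6, grid.n_igf1), dtype=int)
    conv_time = np.empty_like(labels, dtype=float)
    unassigned = []
    for j, il6_0 in enumerate(il6_vals):
        for i, igf1_0 in enumerate(igf1_vals):
            lab, t = _label_initial(igf1_0, il6_0, bp, attractors, t_max)
            labels[j, i] = lab
            conv_time[j, i] = t
            if lab < 0:
                unassigned.append((float(igf1_0), float(il6_0)))
    return PhaseDiagram(
        igf1=igf1_vals, il6=il6_vals, labels=labels, conv_time=conv_time,
        attractors=attractors, unassigned=unassigned,
    )


@dataclass
class SeparatrixCurve:
    """Critical initial-IGF-1 boundary as a function of initial IL-6.

    Each point was bisected along a fixed-IL-6 scan line until the
    bracketing probes (one basin on each side) were closer than ``tol``;
    the stored point is the bracket midpoint.
    """

    il6: np.ndarray
    igf1_crit: np.ndarray
    tol: float
    attractors: list[SteadyState]
    omitted: list[tuple[float, int]] = field(default_factory=list)  # (il6, label)
    igf1_range: tuple[float, float] = C.SCAN_IGF1_RANGE
    il6_range: tuple[float, float] = C.SCAN_IL6_RANGE

    def critical_igf1(self, il6: float) -> float:
        """Critical IGF-1 at the given IL-6.

        Within the scanned boundary points this is linear interpolation.
        Beyond them the single-basin scan lines recorded in ``omitted``
        pin the geometry: above the first all-frail line the boundary has
        left the top of the IGF-1 window (+inf, everything frail), below
        the last all-mobile line it has left the bottom (-inf); the
        strips in between interpolate toward the window edge.
        """
        if len(self.il6) == 0:
            raise ValueError("empty separatrix (monostable parameters?)")
        if self.il6[0] <= il6 <= self.il6[-1]:
            return float(np.interp(il6, self.il6, self.igf1_crit))
        if il6 > self.il6[-1]:
            frail_above = [v for v, lab in self.omitted if v > self.il6[-1] and lab == 0]
            if not frail_above:
                return float(self.igf1_crit[-1])
            edge = min(frail_above)
            if il6 >= edge:
                return math.inf
            return float(np.interp(il6, [self.il6[-1], edge],
                                   [self.igf1_crit[-1], self.igf1_range[1]]))
        mobile_below = [v for v, lab in self.omitted if v < self.il6[0] and lab == 1]
        if not mobile_below:
            return float(self.igf1_crit[0])
        edge = max(mobile_below)
        if il6 <= edge:
            return -math.inf
        return float(np.interp(il6, [edge, self.il6[0]],
                               [self.igf1_range[0], self.igf1_crit[0]]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"IL6_0": self.il6, "IGF1_crit": self.igf1_crit})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def find_separatrix(
    bp: BiomarkerParams,
    igf1_range: tuple[float, float] = C.SCAN_IGF1_RANGE,
    il6_range: tuple[float, float] = C.SCAN_IL6_RANGE,
    n_lines: int = 25,
    tol: float | None = None,
    t_max: float = 1e4,
) -> SeparatrixCurve:
    """Bisect the basin boundary along fixed-IL-6 scan lines.

    Scan lines on which both range endpoints converge to the same
    attractor contribute no point; they are recorded in ``omitted`` with
    their single basin label and logged.
    """
    if tol is None:
        tol = 1e-3 * (igf1_range[1] - igf1_range[0])
    attractors = stable_states(find_biomarker_steady_states(bp))
    if len(attractors) < 2:
        return SeparatrixCurve(
            il6=np.array([]), igf1_crit=np.array([]), tol=tol,
            attractors=attractors, igf1_range=igf1_range, il6_range=il6_range,
        )
    il6_lines = np.linspace(*il6_range, n_lines)
    pts_il6, pts_igf1, omitted = [], [], []
    for il6_0 in il6_lines:
        lo, hi = igf1_range
        lab_lo, _ = _label_initial(lo, il6_0, bp, attractors, t_max)
        lab_hi, _ = _label_initial(hi, il6_0, bp, attractors, t_max)
        if lab_lo == lab_hi or -1 in (lab_lo, lab_hi):
            omitted.append((float(il6_0), int(lab_lo)))
            logger.info("scan line IL6=%.3g has a single basin (label %d)",
                        il6_0, lab_lo)
            continue
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            lab_mid, _ = _label_initial(mid, il6_0, bp, attractors, t_max)
            if lab_mid == lab_lo:
                lo = mid
            else:
                hi = mid
        pts_il6.append(float(il6_0))
        pts_igf1.append(0.5 * (lo + hi))
    return SeparatrixCurve(
        il6=np.asarray(pts_il6), igf1_crit=np.asarray(pts_igf1), tol=tol,
        attractors=attractors, omitted=omitted,
        igf1_range=igf1_range, il6_range=il6_range,
    )


@dataclass
class SwitchCurve:
    """Mobility prevalence vs one initial biomarker at several horizons.

    ``M`` is the raw prevalence score (which carries the Gompertz
    survival factor and hence decays toward zero near the population
    extinction horizon); ``mobile_given_alive`` is the mobility fraction
    among survivors, the quantity that stays meaningful at long horizons
    and converges to the basin indicator.  Critical values and steepness
    are measured on the survivor-conditional curve normalized by its own
    maximum.
    """

    vary: str                      # "IGF1" or "IL6"
    fixed_value: float
    values: np.ndarray             # swept initial values
    horizons: tuple[float, ...]    # months, increasing
    M: np.ndarray                  # raw prevalence, shape (n_horizons, n_values)
    mobile_given_alive: np.ndarray  # same shape
    criticals: dict[float, float | None]
    steepness: dict[float, float]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.vary + "_0": self.values})
        for k, h in enumerate(self.horizons):
            df[f"M_{h:g}mo"] = self.M[k]
            df[f"M_given_alive_{h:g}mo"] = self.mobile_given_alive[k]
        return df


def _detect_threshold(x: np.ndarray, m: np.ndarray) -> tuple[float | None, float]:
    """Steepest-gradient midpoint of the normalized curve, or None.

    A transition is declared when the curve normalized by its maximum
    spans more than 0.5; otherwise the curve is considered threshold-free
    (flat or gently graded).
    """
    mmax = float(m.max())
    if mmax <= 1e-300:
        return None, 0.0
    mn = m / mmax
    steps = np.abs(np.diff(mn))
    dx = np.abs(np.diff(x))
    steepness = float(np.max(steps / dx))
    if mn.max() - mn.min() < 0.5:
        return None, steepness
    k = int(np.argmax(steps))
    return float(0.5 * (x[k] + x[k + 1])), steepness


def mobility_switch_curve(
    vary: str,
    bp: BiomarkerParams,
    op: OutcomeParams,
    fixed_value: float | None = None,
    horizons: tuple[float, ...] = (60.0, 240.0, 360.0),
    sweep_range: tuple[float, float] | None = None,
    n_sweep: int = 400,
    M0: float = 1.0,
    MD0: float = 0.0,
) -> SwitchCurve:
    """Sweep one biomarker's initial value; record M at each horizon.

    Defaults follow the population means: the fixed biomarker sits at
    3.14 pg/ml (IL-6) or 107.8 ng/ml (IGF-1), and the sweep covers the
    paper-style initial-condition range of the varied biomarker.
    """
    if vary not in ("IGF1", "IL6"):
        raise ValueError("vary must be 'IGF1' or 'IL6'")
    if tuple(sorted(horizons)) != tuple(horizons):
        raise ValueError("horizons must be increasing")
    if fixed_value is None:
        fixed_value = C.MEAN_IL6 if vary == "IGF1" else C.MEAN_IGF1
    if sweep_range is None:
        sweep_range = C.SCAN_IGF1_RANGE if vary == "IGF1" else C.SCAN_IL6_RANGE
    values = np.linspace(*sweep_range, n_sweep)
    t_grid = np.unique(np.concatenate([[0.0], np.asarray(horizons, float)]))
    idx = [int(np.argmin(np.abs(t_grid - h))) for h in horizons]
    M = np.empty((len(horizons), n_sweep))
    phi = np.empty_like(M)
    survival0 = M0 + MD0
    phi0 = M0 / survival0 if survival0 > 0 else 1.0

    # reduced dynamics of (biomarkers, mobile-fraction-among-survivors,
    # log survival): exact transform of the 5-D system that stays
    # well-conditioned long after the Gompertz extinction of raw M
    from .model import _biomarker_derivs

    def rhs(t, y):
        x = max(y[0], 0.0)
        z = max(y[1], 0.0)
        f = min(max(y[2], 0.0), 1.0)
        dx, dz = _biomarker_derivs(x, z, bp)
        h = op.k_mort * np.exp(min(op.k_longevity * t, 500.0))
        df = (-op.k_loss * z * f + op.k_gain * x * (1.0 - f)
              + h * (op.k_extra - 1.0) * f * (1.0 - f))
        dlns = -h * (f + op.k_extra * (1.0 - f))
        return (dx, dz, df, dlns)

    for i, v in enumerate(values):
        igf1_0, il6_0 = (v, fixed_value) if vary == "IGF1" else (fixed_value, v)
        sol = solve_ivp(rhs, (0.0, float(t_grid[-1])), [igf1_0, il6_0, phi0, 0.0],
                        t_eval=t_grid, method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise SimulationError(f"switch-curve integration failed at {vary}={v}")
        for k, j in enumerate(idx):
            phi[k, i] = sol.y[2][j]
            M[k, i] = sol.y[2][j] * survival0 * np.exp(sol.y[3][j])
    criticals, steepness = {}, {}
    for k, h in enumerate(horizons):
        crit, s = _detect_threshold(values, phi[k])
        criticals[h] = crit
        steepness[h] = s
    return SwitchCurve(
        vary=vary, fixed_value=float(fixed_value), values=values,
        horizons=tuple(horizons), M=M, mobile_given_alive=phi,
        criticals=criticals, steepness=steepness,
    )


def critical_threshold(curve: SwitchCurve, horizon: float) -> float | None:
    """Per-horizon critical initial value, or None when no transition exists."""
    if horizon not in curve.criticals:
        raise KeyError(f"horizon {horizon} not in curve {tuple(curve.criticals)}")
    return curve.criticals[horizon]
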