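"""Synthetic study-condition generators.

Everything the pipeline consumes is generated here from the printed
literature constants only: a baseline population of 718 individuals in
four IGF-1 x IL-6 strata (398/128/142/50), the five-year biomarker trend
fixture, and per-cohort Gompertz survival / disability fixtures with a
2.5x extreme-cohort five-year mortality ratio and pooled extinction at
240 months.

Distribution choices (not printed anywhere, flagged synthetic):
IGF-1 is truncated normal per stratum over the observed 40-300 ng/ml
range; IL-6 is truncated log-normal (right-skewed cytokine) over
0.4-15 pg/ml.  One location parameter per biomarker (the high-side
stratum) is solved so the expected pooled means equal 107.8 ng/ml and
3.14 pg/ml exactly.  Within-stratum sampling uses jittered-stratified
uniforms through the inverse CDF — standard stratified Monte Carlo, so
pooled sample means deviate from their targets by O(1/n), not O(1/sqrt n).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from . import constants as C
from .calibrate import CohortOutcomeFixture, TrendFixture
from .outcomes import CohortDefinition, stratify_population

__all__ = [
    "PopulationSpec",
    "FixtureBundle",
    "generate_population",
    "generate_trend_fixture",
    "generate_outcome_fixtures",
    "generate_all",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Design of the synthetic baseline population."""

    n: int = C.TOTAL_N
    counts: tuple[tuple[str, int], ...] = tuple(C.COHORT_COUNTS.items())
    cutoff_igf1: float = 85.0   # ng/ml, low/high IGF-1 boundary (~25th pct)
    cutoff_il6: float = 4.5     # pg/ml, low/high IL-6 boundary (~75th pct)
    igf1_bounds: tuple[float, float] = (40.0, 300.0)
    il6_bounds: tuple[float, float] = (0.4, 15.0)
    mean_igf1: float = C.MEAN_IGF1
    mean_il6: float = C.MEAN_IL6
    # fixed low-side distribution parameters; the high-side locations are
    # solved so the pooled expectation hits the target means exactly
    low_igf1_loc: float = 70.0
    low_igf1_scale: float = 15.0
    high_igf1_scale: float = 40.0
    low_il6_mu: float = math.log(2.0)
    il6_sigma: float = 0.5

    def __post_init__(self):
        if sum(n for _, n in self.counts) != self.n:
            raise ValueError("per-cohort counts must sum to n")
        if not (self.igf1_bounds[0] < self.cutoff_igf1 < self.igf1_bounds[1]):
            raise ValueError("cutoff_igf1 outside the population bounds")
        if not (self.il6_bounds[0] < self.cutoff_il6 < self.il6_bounds[1]):
            raise ValueError("cutoff_il6 outside the population bounds")

    @property
    def counts_dict(self) -> dict[str, int]:
        return dict(self.counts)


def _truncnorm_mean(loc, scale, lo, hi) -> float:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return float(truncnorm.mean(a, b, loc=loc, scale=scale))


def _truncnorm_ppf(u, loc, scale, lo, hi):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _interval_mass(a, b) -> float:
    # P(a < Z < b) evaluated in the numerically safer tail
    if a > 0:
        return float(norm.sf(a) - norm.sf(b))
    return float(norm.cdf(b) - norm.cdf(a))


def _trunc_lognorm_mean(mu, sigma, lo, hi) -> float:
    # E[e^X] for X ~ Normal(mu, sigma) truncated to [ln lo, ln hi]
    a, b = (math.log(lo) - mu) / sigma, (math.log(hi) - mu) / sigma
    z = _interval_mass(a, b)
    if z <= 0:
        raise ValueError("empty truncation interval")
    shifted = _interval_mass(a - sigma, b - sigma)
    return math.exp(mu + 0.5 * sigma**2) * shifted / z


def _trunc_lognorm_ppf(u, mu, sigma, lo, hi):
    a, b = (math.log(lo) - mu) / sigma, (math.log(hi) - mu) / sigma
    return np.exp(truncnorm.ppf(u, a, b, loc=mu, scale=sigma))


def _solve_high_igf1_loc(spec: PopulationSpec) -> float:
    counts = spec.counts_dict
    n_low = counts["lowIGF_lowIL6"] + counts["lowIGF_highIL6"]
    n_high = spec.n - n_low
    m_low = _truncnorm_mean(spec.low_igf1_loc, spec.low_igf1_scale,
                            spec.igf1_bounds[0], spec.cutoff_igf1)
    target_high = (spec.mean_igf1 * spec.n - n_low * m_low) / n_high

    def f(loc):
        return _truncnorm_mean(loc, spec.high_igf1_scale,
                               spec.cutoff_igf1, spec.igf1_bounds[1]) - target_high

    lo, hi = spec.cutoff_igf1 - 200.0, spec.igf1_bounds[1] + 200.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"infeasible high-IGF-1 stratum: required stratum mean {target_high:.1f}"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def _solve_high_il6_mu(spec: PopulationSpec) -> float:
    counts = spec.counts_dict
    n_high = counts["highIGF_highIL6"] + counts["lowIGF_highIL6"]
    n_low = spec.n - n_high
    m_low = _trunc_lognorm_mean(spec.low_il6_mu, spec.il6_sigma,
                                spec.il6_bounds[0], spec.cutoff_il6)
    target_high = (spec.mean_il6 * spec.n - n_low * m_low) / n_high

    def f(mu):
        return _trunc_lognorm_mean(mu, spec.il6_sigma,
                                   spec.cutoff_il6, spec.il6_bounds[1]) - target_high

    lo, hi = math.log(spec.cutoff_il6) - 6.0, math.log(spec.il6_bounds[1]) + 6.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"infeasible high-IL-6 stratum: required stratum mean {target_high:.2f}"
        )
    return brentq(f, lo, hi, xtol=1e-12)


def _stratified_uniforms(n: int, rng: np.random.Generator) -> np.ndarray:
    u = (np.arange(n) + rng.random(n)) / n
    return rng.permutation(u)


def generate_population(
    spec: PopulationSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Sample the baseline population with exact per-cohort counts.

    Returns a DataFrame with columns id, cohort, IGF1, IL6; the spec,
    cut-offs and solved distribution parameters are stored in
    ``df.attrs``.
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(seed)
    high_igf1_loc = _solve_high_igf1_loc(spec)
    high_il6_mu = _solve_high_il6_mu(spec)

    rows = []
    for label, n_c in spec.counts:
        if n_c <= 0:
            raise ValueError(f"stratum {label} has non-positive count")
        u_igf1 = _stratified_uniforms(n_c, rng)
        u_il6 = _stratified_uniforms(n_c, rng)
        if label.startswith("highIGF"):
            igf1 = _truncnorm_ppf(u_igf1, high_igf1_loc, spec.high_igf1_scale,
                                  spec.cutoff_igf1, spec.igf1_bounds[1])
        else:
            igf1 = _truncnorm_ppf(u_igf1, spec.low_igf1_loc, spec.low_igf1_scale,
                                  spec.igf1_bounds[0], spec.cutoff_igf1)
        if label.endswith("highIL6"):
            il6 = _trunc_lognorm_ppf(u_il6, high_il6_mu, spec.il6_sigma,
                                     spec.cutoff_il6, spec.il6_bounds[1])
        else:
            il6 = _trunc_lognorm_ppf(u_il6, spec.low_il6_mu, spec.il6_sigma,
                                     spec.il6_bounds[0], spec.cutoff_il6)
        rows.append(pd.DataFrame({"cohort": label, "IGF1": igf1, "IL6": il6}))
    df = pd.concat(rows, ignore_index=True)
    df = df.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)
    df.insert(0, "id", np.arange(len(df)))
    df.attrs.update(
        {
            "seed": seed,
            "cutoff_igf1": spec.cutoff_igf1,
            "cutoff_il6": spec.cutoff_il6,
            "igf1_bounds": spec.igf1_bounds,
            "il6_bounds": spec.il6_bounds,
            "high_igf1_loc": high_igf1_loc,
            "high_il6_mu": high_il6_mu,
            "spec": spec,
        }
    )
    return df


def generate_trend_fixture(
    baselines: tuple[float, float] = (C.MEAN_IGF1, C.MEAN_IL6),
    slopes_per_year: tuple[float, float] = (C.IGF1_SLOPE_PER_YEAR, C.IL6_SLOPE_PER_YEAR),
    horizon: float = 60.0,
    n_points: int = 61,
    noise_sd: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> TrendFixture:
    """Linear biomarker trend series (noise-free by default)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t = np.linspace(0.0, horizon, n_points)
    igf1 = baselines[0] + slopes_per_year[0] * t / C.MONTHS_PER_YEAR
    il6 = baselines[1] + slopes_per_year[1] * t / C.MONTHS_PER_YEAR
    if any(s > 0 for s in noise_sd):
        rng = np.random.default_rng(seed)
        igf1 = igf1 + rng.normal(0.0, noise_sd[0], n_points)
        il6 = il6 + rng.normal(0.0, noise_sd[1], n_points)
    clipped = bool(np.any(igf1 < 0) or np.any(il6 < 0))
    if clipped:
        import warnings

        warnings.warn("projected concentrations went negative; truncated at 0")
        igf1, il6 = np.maximum(igf1, 0.0), np.maximum(il6, 0.0)
    fx = TrendFixture(
        t=t, igf1=igf1, il6=il6, noise_sd=noise_sd,
        meta={
            "baselines": baselines, "slopes_per_year": slopes_per_year,
            "seed": seed, "clipped": clipped,
            "formula": "x(t) = x0 + slope * t_months / 12",
        },
    )
    fx.validate()
    return fx


def _gompertz_survival(t, a, b):
    return np.exp(-(a / b) * np.expm1(b * t))


def _gompertz_rate_for_mortality(m60, b, horizon=60.0):
    # a such that 1 - S(horizon) = m60 under hazard a*e^{bt}
    return -math.log(1.0 - m60) * b / math.expm1(b * horizon)


def generate_outcome_fixtures(
    cohorts: dict[str, CohortDefinition],
    mortality_ratio: float = C.MORTALITY_RATIO_5Y,
    best_mortality_60: float = 0.16,
    horizon: float = 60.0,
    longevity_horizon: float = C.LONGEVITY_HORIZON_MONTHS,
    extinction_tol: float = C.EXTINCTION_TOL,
    disabled_frac_0: tuple[float, float, float, float] = (0.05, 0.10, 0.15, 0.30),
    disabled_frac_36: tuple[float, float, float, float] = (0.06, 0.16, 0.28, 0.60),
    n_points: int = 61,
) -> list[CohortOutcomeFixture]:
    """Per-cohort Gompertz survival fixtures over 60 months.

    The four cohorts share one Gompertz shape parameter b, solved so the
    count-weighted pooled survival reaches ``extinction_tol`` exactly at
    ``longevity_horizon``; per-cohort scales are solved so cumulative
    60-month mortality interpolates geometrically between the best
    cohort (``best_mortality_60``) and ``mortality_ratio`` times that in
    the worst cohort.  Disabled fractions are monotone in the clinical
    risk ordering.

    ``cohorts`` is the output of :func:`frailswitch.outcomes.stratify_population`.
    """
    if mortality_ratio < 1.0:
        raise ValueError("mortality_ratio must be >= 1")
    worst_m = best_mortality_60 * mortality_ratio
    if worst_m >= 1.0:
        raise ValueError(
            f"infeasible ratio: worst-cohort 60-month mortality {worst_m} >= 1"
        )
    labels = list(C.RISK_ORDER)
    missing = [lab for lab in labels if lab not in cohorts]
    if missing:
        raise ValueError(f"cohorts missing strata: {missing}")
    theta = {lab: i / (len(labels) - 1) for i, lab in enumerate(labels)}
    m60 = {lab: best_mortality_60 * mortality_ratio ** theta[lab] for lab in labels}
    weights = {lab: cohorts[lab].n for lab in labels}
    total = sum(weights.values())

    def pooled_at_horizon(b):
        s = 0.0
        for lab in labels:
            a = _gompertz_rate_for_mortality(m60[lab], b, horizon)
            s += weights[lab] / total * _gompertz_survival(longevity_horizon, a, b)
        return s - extinction_tol

    lo, hi = 1e-5, 0.2
    if pooled_at_horizon(lo) < 0 or pooled_at_horizon(hi) > 0:
        raise ValueError(
            f"infeasible ratio/horizon combination: cannot reach pooled survival "
            f"{extinction_tol} at {longevity_horizon} months"
        )
    b = brentq(pooled_at_horizon, lo, hi, xtol=1e-14)

    t = np.linspace(0.0, horizon, n_points)
    fixtures = []
    for i, lab in enumerate(labels):
        a = _gompertz_rate_for_mortality(m60[lab], b, horizon)
        fx = CohortOutcomeFixture(
            label=lab,
            n=cohorts[lab].n,
            t=t,
            survival=_gompertz_survival(t, a, b),
            disabled_frac_0=disabled_frac_0[i],
            disabled_frac_36=disabled_frac_36[i],
            baseline_igf1=cohorts[lab].mean_igf1,
            baseline_il6=cohorts[lab].mean_il6,
            interpolated=True,
            meta={
                "gompertz_a": a, "gompertz_b": b, "mortality_60": m60[lab],
                "risk_exponent": theta[lab], "mortality_ratio": mortality_ratio,
            },
        )
        fx.validate()
        fixtures.append(fx)
    return fixtures


@dataclass
class FixtureBundle:
    """Everything the calibration consumes, plus generation metadata."""

    population: pd.DataFrame
    cohorts: dict[str, CohortDefinition]
    trend: TrendFixture
    outcome_fixtures: list[CohortOutcomeFixture]
    metadata: dict = field(default_factory=dict)

    def write_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(outdir / "population.csv", index=False)
        self.trend.to_csv(outdir / "trend.csv")
        for fx in self.outcome_fixtures:
            fx.to_csv(outdir / f"cohort_{fx.label}.csv")
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True, default=str)


def generate_all(
    seed: int = 0,
    spec: PopulationSpec | None = None,
    disabled_frac_0: tuple[float, float, float, float] = (0.05, 0.10, 0.15, 0.30),
    disabled_frac_36: tuple[float, float, float, float] = (0.06, 0.16, 0.28, 0.60),
    best_mortality_60: float = 0.16,
) -> FixtureBundle:
    """Population + trend + outcome fixtures in one deterministic call."""
    spec = spec or PopulationSpec()
    pop = generate_population(spec, seed=seed)
    cohorts = stratify_population(pop, spec.cutoff_igf1, spec.cutoff_il6)
    trend = generate_trend_fixture()
    fixtures = generate_outcome_fixtures(
        cohorts,
        disabled_frac_0=disabled_frac_0,
        disabled_frac_36=disabled_frac_36,
        best_mortality_60=best_mortality_60,
    )
    meta = {
        "seed": seed,
        "cutoffs": {"IGF1": spec.cutoff_igf1, "IL6": spec.cutoff_il6},
        "counts": spec.counts_dict,
        "constants": {
            "mean_igf1": spec.mean_igf1, "mean_il6": spec.mean_il6,
            "slopes_per_year": (C.IGF1_SLOPE_PER_YEAR, C.IL6_SLOPE_PER_YEAR),
            "mortality_ratio": C.MORTALITY_RATIO_5Y,
            "longevity_horizon": C.LONGEVITY_HORIZON_MONTHS,
            "extinction_tol": C.EXTINCTION_TOL,
            "k_extra": C.K_EXTRA,
        },
    }
    return FixtureBundle(pop, cohorts, trend, fixtures, meta)
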