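"""End-to-end orchestration: generate -> calibrate -> scan -> separatrix ->
switch curves -> cohorts -> report.

Every output is regenerable from (config, seed) alone; the summary JSON
is deterministic (sorted keys, no timestamps — stage timings go to the
log, not the summary).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import constants as C
from .bistability import (
    InitialGrid,
    find_separatrix,
    mobility_switch_curve,
    scan_attractors,
)
from .calibrate import calibrate_all, pooled_extinction_time, _cohort_initial
from .model import (
    StateVector,
    find_biomarker_steady_states,
    save_parameters,
    simulate,
    stable_states,
)
from .outcomes import classify_phenotype, death_state_decomposition, simulate_cohort
from .synthetic import PopulationSpec, generate_all

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Paths, seed, solver/scan resolutions and the constants block.

    The constants default to the printed literature values; any override
    is logged at WARNING level.
    """

    outdir: str = "frailswitch_out"
    seed: int = 0
    hill_n: int = 2
    scan_n_igf1: int = 60
    scan_n_il6: int = 60
    separatrix_lines: int = 25
    sweep_n: int = 400
    switch_horizons: tuple[float, ...] = (60.0, 240.0, 360.0)
    cohort_horizon: float = 360.0
    calib_inhibition_starts: int = 8
    calib_outcome_starts: int = 4
    calib_outer_iters: int = 3
    make_plots: bool = True
    constants: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("switch_horizons",):
            if key in doc:
                doc[key] = tuple(doc[key])
        cfg = cls(**doc)
        for key, val in cfg.constants.items():
            logger.warning("constant override: %s = %r", key, val)
        return cfg


def _plot_all(outdir: Path, diagram, sep, curves, envelopes) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.pcolormesh(diagram.igf1, diagram.il6, diagram.labels, shading="nearest",
                  cmap="RdYlGn", vmin=-1, vmax=1)
    if sep is not None and len(sep.il6):
        ax.plot(sep.igf1_crit, sep.il6, "k-", lw=2, label="critical threshold")
        ax.legend()
    ax.set_xlabel("initial IGF-1 (ng/ml)")
    ax.set_ylabel("initial IL-6 (pg/ml)")
    ax.set_title("Basins of attraction")
    fig.savefig(outdir / "phase_plane.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(curves), figsize=(6 * len(curves), 4))
    for ax, curve in zip(np.atleast_1d(axes), curves):
        for k, h in enumerate(curve.horizons):
            ax.plot(curve.values, curve.M[k], label=f"{h / 12:g} y")
        ax.set_xlabel(f"initial {curve.vary}")
        ax.set_ylabel("prevalence score of mobility")
        ax.legend()
    fig.savefig(outdir / "switch_curves.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    for ax, (label, env) in zip(axes.ravel(), envelopes.items()):
        ax.plot(env.mean.t, env.mean.M, "-", label="mean")
        ax.plot(env.best.t, env.best.M, "--", label="best corner")
        ax.plot(env.worst.t, env.worst.M, "--", label="worst corner")
        ax.fill_between(env.mean.t, env.worst.M, env.best.M, alpha=0.2)
        ax.set_title(label)
        ax.set_xlabel("months")
        ax.set_ylabel("M")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "cohort_envelopes.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write CSV/JSON/PNG outputs; return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                     "hill_n": config.hill_n}
    stage = "generate"
    try:
        t0 = time.perf_counter()
        bundle = generate_all(seed=config.seed)
        bundle.write_dir(outdir / "fixtures")
        pop = bundle.population
        summary["cohort_counts"] = {k: v.n for k, v in bundle.cohorts.items()}
        summary["pooled_mean_IGF1"] = float(pop["IGF1"].mean())
        summary["pooled_mean_IL6"] = float(pop["IL6"].mean())
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "calibrate"
        t0 = time.perf_counter()
        require_bistable = config.hill_n == 2
        result = calibrate_all(
            bundle.trend, bundle.outcome_fixtures, seed=config.seed,
            hill_n=config.hill_n, require_bistable=require_bistable,
            inhibition_starts=config.calib_inhibition_starts,
            outcome_starts=config.calib_outcome_starts,
            outer_iters=config.calib_outer_iters,
        )
        bp, op = result.biomarker, result.outcome
        save_parameters(outdir / "params.json", bp, op,
                        extra={"seed": config.seed})
        summary["bistable"] = result.bistable
        states = find_biomarker_steady_states(bp)
        summary["n_stable_states"] = len(stable_states(states))
        summary["steady_states"] = [
            {"IGF1": s.IGF1_star, "IL6": s.IL6_star, "stability": s.stability}
            for s in states
        ]
        if not result.bistable:
            warnings.warn("calibrated biomarker subsystem is not bistable")
            summary["warning"] = "not bistable"
        # trend reproduction
        from .model import simulate_biomarkers

        igf1, il6 = simulate_biomarkers(
            bundle.trend.igf1[0], bundle.trend.il6[0], bp, bundle.trend.t
        )
        years = (bundle.trend.t[-1] - bundle.trend.t[0]) / C.MONTHS_PER_YEAR
        summary["sim_igf1_slope_per_year"] = float((igf1[-1] - igf1[0]) / years)
        summary["sim_il6_slope_per_year"] = float((il6[-1] - il6[0]) / years)
        # pooled extinction + cohort mortality ratio
        summary["extinction_month"] = float(
            pooled_extinction_time(bundle.outcome_fixtures, bp, op)
        )
        d60 = {}
        for fx in bundle.outcome_fixtures:
            traj = simulate(_cohort_initial(fx), bp, op, fx.t, validate=False)
            d60[fx.label] = float(traj.D[-1])
        summary["mortality_ratio_60mo"] = (
            d60["lowIGF_highIL6"] / d60["highIGF_lowIL6"]
        )
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "scan"
        t0 = time.perf_counter()
        grid = InitialGrid(n_igf1=config.scan_n_igf1, n_il6=config.scan_n_il6)
        diagram = scan_attractors(grid, bp)
        diagram.to_csv(outdir / "phase_diagram.csv")
        summary["scan_n_attractors"] = int(diagram.n_labels)
        summary["scan_unassigned"] = len(diagram.unassigned)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "separatrix"
        t0 = time.perf_counter()
        sep = None
        if summary["n_stable_states"] == 2:
            sep = find_separatrix(bp, n_lines=config.separatrix_lines)
            sep.to_csv(outdir / "separatrix.csv")
            summary["separatrix_points"] = int(len(sep.il6))
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "switch_curves"
        t0 = time.perf_counter()
        curves = [
            mobility_switch_curve("IGF1", bp, op, horizons=config.switch_horizons,
                                  n_sweep=config.sweep_n),
            mobility_switch_curve("IL6", bp, op, horizons=config.switch_horizons,
                                  n_sweep=config.sweep_n),
        ]
        for curve in curves:
            curve.to_frame().to_csv(outdir / f"switch_{curve.vary}.csv", index=False)
        summary["critical_thresholds"] = {
            curve.vary: {f"{h:g}": curve.criticals[h] for h in curve.horizons}
            for curve in curves
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "cohorts"
        t0 = time.perf_counter()
        envelopes = {}
        for label, cdef in bundle.cohorts.items():
            env = simulate_cohort(cdef, bp, op, horizon=config.cohort_horizon)
            env.to_frame().to_csv(outdir / f"envelope_{label}.csv", index=False)
            envelopes[label] = env
        if sep is not None:
            calls = []
            for _, row in pop.iterrows():
                ph = classify_phenotype((row["IGF1"], row["IL6"]), sep)
                calls.append((int(row["id"]), row["IGF1"], row["IL6"],
                              ph.label, ph.distance))
            import pandas as pd

            pd.DataFrame(
                calls, columns=["id", "IGF1", "IL6", "phenotype", "dist_to_separatrix"]
            ).to_csv(outdir / "phenotypes.csv", index=False)
            frac_frail = sum(1 for c in calls if c[3] == "frail_declining") / len(calls)
            summary["frac_frail_phenotype"] = frac_frail
        decomp = death_state_decomposition(envelopes["highIGF_highIL6"].mean, bp, op)
        summary["mobile_death_fraction_highIGF_highIL6"] = float(
            decomp["mobile_death_fraction"].iloc[-1]
        )
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        if config.make_plots:
            stage = "plots"
            _plot_all(outdir, diagram, sep, curves, envelopes)
    except Exception as err:
        logger.error("pipeline aborted in stage %r: %s", stage, err)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
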