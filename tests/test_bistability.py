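"""Phase-plane analyses: attractor scans, separatrix, switch curves."""

import dataclasses

import numpy as np
import pytest

from frailswitch import (
    BiomarkerParams,
    InitialGrid,
    OutcomeParams,
    critical_threshold,
    find_biomarker_steady_states,
    find_separatrix,
    mobility_switch_curve,
    scan_attractors,
    stable_states,
)
from frailswitch.bistability import _label_initial
from frailswitch.model import integrate_to_steady_state

from conftest import REF_BP, REF_OP, SYM_BP

#: REF_BP sped up 20x (same nullclines, hence identical fixed points and
#: separatrix, but relaxation fast compared to the 5-30 year horizons)
FAST_BP = BiomarkerParams(
    kp_IGF1=400.0 * 0.4, ks_IL6=0.3, kd_IGF1=0.4,
    kp_IL6=25.0 * 0.14, ks_IGF1=5e-4, kd_IL6=0.14,
)

MONO_BP = dataclasses.replace(REF_BP, ks_IL6=0.0, ks_IGF1=0.0)

#: compartment-exchange rates strong enough that the frail/mobile contrast
#: survives the late-time Gompertz survivor-enrichment term
FAST_OP = OutcomeParams(k_loss=0.5, k_gain=0.05, k_mort=0.002,
                        k_longevity=0.0155, k_extra=2.5)


def random_bistable_sets(n, seed=7):
    rng = np.random.default_rng(seed)
    found = []
    while len(found) < n:
        p = BiomarkerParams(
            kp_IGF1=10 ** rng.uniform(0, 2), ks_IL6=10 ** rng.uniform(-2, 1),
            kd_IGF1=10 ** rng.uniform(-2, 0), kp_IL6=10 ** rng.uniform(0, 2),
            ks_IGF1=10 ** rng.uniform(-4, -1), kd_IL6=10 ** rng.uniform(-2, 0),
        )
        if len(stable_states(find_biomarker_steady_states(p))) == 2:
            found.append(p)
    return found


class TestScanAttractors:
    def test_monostable_system_single_label(self):
        grid = InitialGrid(igf1_range=(40, 300), il6_range=(1, 10),
                           n_igf1=6, n_il6=6)
        diagram = scan_attractors(grid, MONO_BP)
        assert diagram.n_labels == 1
        assert not diagram.unassigned

    def test_symmetric_toggle_two_basins(self):
        grid = InitialGrid(igf1_range=(0.02, 1.0), il6_range=(0.02, 1.0),
                           n_igf1=10, n_il6=10)
        diagram = scan_attractors(grid, SYM_BP)
        assert diagram.n_labels == 2
        # nodes exactly on the diagonal sit on the separatrix and converge
        # to the saddle: flagged as unassigned, never silently dropped
        assert all(x == y for x, y in diagram.unassigned)
        # swapping the two species mirrors the basins across the diagonal
        off_diag = ~np.eye(10, dtype=bool)
        assert np.array_equal(diagram.labels[off_diag],
                              (1 - diagram.labels.T)[off_diag])

    def test_row_label_changes_at_most_once(self):
        """Along a fixed-IL-6 row, a 10x finer 1-D sweep confirms a single
        transition in initial IGF-1."""
        attractors = stable_states(find_biomarker_steady_states(SYM_BP))
        il6_0 = 0.35
        coarse = [
            _label_initial(x, il6_0, SYM_BP, attractors)[0]
            for x in np.linspace(0.02, 1.0, 8)
        ]
        fine = [
            _label_initial(x, il6_0, SYM_BP, attractors)[0]
            for x in np.linspace(0.02, 1.0, 80)
        ]
        for labels in (coarse, fine):
            assert sum(a != b for a, b in zip(labels, labels[1:])) <= 1

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            InitialGrid(igf1_range=(300, 40))


class TestSeparatrix:
    def test_symmetric_toggle_boundary_is_diagonal(self):
        sep = find_separatrix(SYM_BP, igf1_range=(0.02, 1.0),
                              il6_range=(0.1, 0.9), n_lines=7)
        assert len(sep.il6) == 7
        assert np.all(np.abs(sep.igf1_crit - sep.il6) <= 2 * sep.tol)

    def test_bracketing_probes_reach_different_basins(self):
        sep = find_separatrix(SYM_BP, igf1_range=(0.02, 1.0),
                              il6_range=(0.2, 0.8), n_lines=5)
        attractors = sep.attractors
        for il6_0, crit in zip(sep.il6, sep.igf1_crit):
            lo = _label_initial(crit - 2 * sep.tol, il6_0, SYM_BP, attractors)[0]
            hi = _label_initial(crit + 2 * sep.tol, il6_0, SYM_BP, attractors)[0]
            assert lo != hi and -1 not in (lo, hi)

    def test_monostable_returns_empty_curve(self):
        sep = find_separatrix(MONO_BP, n_lines=3)
        assert len(sep.il6) == 0
        with pytest.raises(ValueError, match="monostable"):
            sep.critical_igf1(3.0)

    @pytest.mark.parametrize("p", random_bistable_sets(5), ids=lambda p: f"kd={p.kd_IGF1:.3g}")
    def test_consistent_with_grid_scan_on_random_toggles(self, p):
        """Separatrix crossings land inside the label-transition cell of an
        independent attractor-grid scan (oracle equivalence).

        The scan box is centred on the saddle so that it straddles the
        basin boundary whatever the (often very skewed) geometry of the
        random toggle.
        """
        saddle = next(s for s in find_biomarker_steady_states(p)
                      if s.stability == "saddle")
        igf1_range = (max(0.2 * saddle.IGF1_star, 1e-3 * p.igf1_max),
                      min(5.0 * saddle.IGF1_star, p.igf1_max))
        il6_range = (max(0.2 * saddle.IL6_star, 1e-3 * p.il6_max),
                     min(5.0 * saddle.IL6_star, p.il6_max))
        n = 9
        grid = InitialGrid(igf1_range=igf1_range, il6_range=il6_range,
                           n_igf1=n, n_il6=n)
        diagram = scan_attractors(grid, p)
        sep = find_separatrix(p, igf1_range=igf1_range, il6_range=il6_range,
                              n_lines=5)
        cell = (igf1_range[1] - igf1_range[0]) / (n - 1)
        checked = 0
        for j, il6_0 in enumerate(diagram.il6):
            row = diagram.labels[j]
            # slow near-boundary nodes may stay unassigned; bracket the
            # transition by the outermost nodes of each basin
            if row[0] == row[-1] or -1 in (row[0], row[-1]):
                continue
            i_lo = int(np.max(np.nonzero(row == row[0])))
            i_hi = int(np.min(np.nonzero(row == row[-1])))
            assert i_lo < i_hi  # basins are contiguous along the row
            crit = sep.critical_igf1(il6_0)
            assert diagram.igf1[i_lo] - cell <= crit <= diagram.igf1[i_hi] + cell
            checked += 1
        assert checked > 0


class TestSwitchCurve:
    def test_flat_when_outcomes_decoupled(self):
        op = OutcomeParams(k_loss=0.0, k_gain=0.0, k_mort=2e-3,
                           k_longevity=0.0155, k_extra=2.5)
        curve = mobility_switch_curve("IGF1", REF_BP, op, n_sweep=40)
        for k in range(len(curve.horizons)):
            assert np.ptp(curve.M[k]) < 1e-8
        assert all(c is None for c in curve.criticals.values())

    def test_fast_toggle_threshold_matches_separatrix(self):
        """When the toggle relaxes fast compared to the horizons, the
        30-year switch threshold coincides with the separatrix crossing at
        the fixed population-mean IL-6."""
        curve = mobility_switch_curve("IGF1", FAST_BP, FAST_OP, n_sweep=200)
        # bisect the separatrix on the scan line at exactly the fixed IL-6,
        # so no curve-interpolation error enters the comparison
        sep = find_separatrix(FAST_BP, il6_range=(curve.fixed_value, 5.0),
                              n_lines=2)
        step = (curve.values[-1] - curve.values[0]) / (len(curve.values) - 1)
        crit360 = critical_threshold(curve, 360.0)
        assert crit360 is not None
        assert abs(crit360 - sep.critical_igf1(curve.fixed_value)) <= step
        # near-step shape at the longest horizon
        phi = curve.mobile_given_alive[-1]
        assert phi.min() < 0.05 * phi.max()
        assert phi.max() > 0.9
        # sharpening over time; by 240 months the fast toggle's transition
        # is a single-step jump, so steepness saturates at the sweep
        # resolution rather than strictly increasing further
        s = [curve.steepness[h] for h in curve.horizons]
        assert s[0] < s[1]
        assert s[2] >= 0.95 * s[1]

    def test_threshold_stable_under_resolution_doubling(self):
        coarse = mobility_switch_curve("IGF1", FAST_BP, FAST_OP, n_sweep=100)
        fine = mobility_switch_curve("IGF1", FAST_BP, FAST_OP, n_sweep=200)
        step = (coarse.values[-1] - coarse.values[0]) / 99
        for h in coarse.horizons:
            assert abs(coarse.criticals[h] - fine.criticals[h]) <= step

    def test_calibrated_steepness_increases_and_converges(self, calibrated,
                                                          separatrix_cal):
        """With calibrated (slow) dynamics, transitions sharpen with horizon
        and the per-horizon thresholds move monotonically toward the
        separatrix crossing."""
        bp, op = calibrated.biomarker, calibrated.outcome
        curve = mobility_switch_curve("IGF1", bp, op, n_sweep=150)
        s = [curve.steepness[h] for h in curve.horizons]
        assert s[0] < s[1] < s[2]
        target = separatrix_cal.critical_igf1(curve.fixed_value)
        gaps = [abs(curve.criticals[h] - target)
                for h in curve.horizons if curve.criticals[h] is not None]
        assert len(gaps) >= 2
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert np.all((curve.M >= 0) & (curve.M <= 1 + 1e-9))

    def test_monostable_has_no_threshold(self):
        curve = mobility_switch_curve("IGF1", MONO_BP, REF_OP, n_sweep=60)
        assert all(c is None for c in curve.criticals.values())

    def test_unknown_horizon_rejected(self):
        curve = mobility_switch_curve("IGF1", FAST_BP, FAST_OP, n_sweep=30)
        with pytest.raises(KeyError):
            critical_threshold(curve, 123.0)

    def test_vary_must_be_biomarker(self):
        with pytest.raises(ValueError):
            mobility_switch_curve("XYZ", REF_BP, REF_OP)


class TestHillSensitivity:
    def test_hill_one_is_monostable(self):
        p1 = dataclasses.replace(REF_BP, hill_n=1)
        assert len(stable_states(find_biomarker_steady_states(p1))) == 1
        grid = InitialGrid(igf1_range=(40, 300), il6_range=(1, 10),
                           n_igf1=5, n_il6=5)
        assert scan_attractors(grid, p1).n_labels == 1
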