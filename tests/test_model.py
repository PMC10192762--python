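"""Core model: right-hand sides, integration, steady states, survival law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frailswitch import (
    BiomarkerParams,
    OutcomeParams,
    StateVector,
    biomarker_rhs,
    closed_form_survival,
    find_biomarker_steady_states,
    load_parameters,
    outcome_rhs,
    save_parameters,
    simulate,
    stable_states,
)

from conftest import REF_BP, SYM_BP


def bisect_root(f, lo, hi, iters=200):
    """Plain bisection, independent of any scipy machinery."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) * flo <= 0:
            hi = mid
        else:
            lo = mid
            flo = f(lo)
    return 0.5 * (lo + hi)


class TestBiomarkerRHS:
    def test_zero_inhibitor_reduces_to_linear_kinetics(self):
        p = REF_BP
        state = StateVector(t=0.0, IGF1=150.0, IL6=0.0)
        digf1, _ = biomarker_rhs(state, p)
        assert digf1 == pytest.approx(p.kp_IGF1 - p.kd_IGF1 * 150.0, rel=1e-14)

    def test_uninhibited_fixed_point(self):
        p = REF_BP
        state = StateVector(t=0.0, IGF1=p.kp_IGF1 / p.kd_IGF1, IL6=0.0)
        digf1, _ = biomarker_rhs(state, p)
        assert digf1 == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_fixed_point_matches_scalar_oracle(self):
        # the symmetric toggle's middle fixed point solves 10 x^3 + x = 1
        root = bisect_root(lambda x: 10 * x**3 + x - 1, 0.0, 1.0)
        assert root == pytest.approx(0.39301, abs=1e-4)
        state = StateVector(t=0.0, IGF1=root, IL6=root)
        dx, dy = biomarker_rhs(state, SYM_BP)
        assert abs(dx) < 1e-12 and abs(dy) < 1e-12

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            biomarker_rhs(StateVector(t=0.0, IGF1=-1.0, IL6=2.0), REF_BP)


class TestOutcomeRHS:
    @given(
        m=st.floats(0.0, 1.0),
        split=st.floats(0.0, 1.0),
        igf1=st.floats(0.0, 400.0),
        il6=st.floats(0.0, 25.0),
        t=st.floats(0.0, 240.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_conservation_and_monotone_death(self, m, split, igf1, il6, t):
        md = (1.0 - m) * split
        d = 1.0 - m - md
        state = StateVector(t=t, IGF1=igf1, IL6=il6, M=m, MD=md, D=d)
        op = OutcomeParams(k_loss=0.01, k_gain=5e-4, k_mort=2e-3,
                           k_longevity=0.015, k_extra=2.5)
        dm, dmd, dd = outcome_rhs(state, REF_BP, op)
        assert dm + dmd + dd == 0.0  # exact by construction
        assert dd >= 0.0

    def test_frozen_dynamics(self):
        op = OutcomeParams(k_loss=0.0, k_gain=0.0, k_mort=0.0,
                           k_longevity=0.0, k_extra=2.5)
        state = StateVector(t=12.0, IGF1=100.0, IL6=3.0, M=0.6, MD=0.3, D=0.1)
        assert outcome_rhs(state, REF_BP, op) == (0.0, 0.0, 0.0)

    def test_single_compartment_mortality(self):
        op = OutcomeParams(k_loss=0.0, k_gain=1e-3, k_mort=2e-3,
                           k_longevity=0.01, k_extra=2.5)
        state = StateVector(t=50.0, IGF1=100.0, IL6=3.0, M=1.0, MD=0.0, D=0.0)
        _, _, dd = outcome_rhs(state, REF_BP, op)
        assert dd == pytest.approx(op.k_mort * math.exp(op.k_longevity * 50.0),
                                   rel=1e-12)

    def test_disabled_hazard_amplified_by_k_extra(self):
        op = OutcomeParams(k_loss=0.0, k_gain=0.0, k_mort=2e-3,
                           k_longevity=0.01, k_extra=2.5)
        mobile = StateVector(t=30.0, IGF1=1.0, IL6=1.0, M=1.0, MD=0.0, D=0.0)
        disabled = StateVector(t=30.0, IGF1=1.0, IL6=1.0, M=0.0, MD=1.0, D=0.0)
        dd_mobile = outcome_rhs(mobile, REF_BP, op)[2]
        dd_disabled = outcome_rhs(disabled, REF_BP, op)[2]
        assert dd_disabled / dd_mobile == pytest.approx(2.5, rel=1e-12)


class TestSimulate:
    def test_matches_gompertz_closed_form(self):
        op = OutcomeParams(k_loss=0.0, k_gain=0.0, k_mort=2e-3,
                           k_longevity=0.0155, k_extra=2.5)
        t = np.linspace(0.0, 240.0, 241)
        traj = simulate(StateVector(t=0.0, IGF1=107.8, IL6=3.14), REF_BP, op, t)
        expect = closed_form_survival(t, op.k_mort, op.k_longevity, M0=1.0)
        assert np.max(np.abs(traj.M - expect) / expect) < 1e-6

    def test_frozen_outcomes_stay_constant(self):
        op = OutcomeParams(k_loss=0.0, k_gain=0.0, k_mort=0.0,
                           k_longevity=0.0, k_extra=2.5)
        t = np.linspace(0.0, 240.0, 121)
        traj = simulate(
            StateVector(t=0.0, IGF1=107.8, IL6=3.14, M=0.7, MD=0.2, D=0.1),
            REF_BP, op, t,
        )
        assert np.allclose(traj.M, 0.7, atol=1e-9)
        assert np.allclose(traj.MD, 0.2, atol=1e-9)
        assert np.allclose(traj.D, 0.1, atol=1e-9)

    def test_trajectory_invariants_and_csv_schema(self, tmp_path, ref_outcome):
        t = np.linspace(0.0, 300.0, 301)
        traj = simulate(StateVector(t=0.0, IGF1=80.0, IL6=5.0, M=0.9, MD=0.1),
                        REF_BP, ref_outcome, t)
        assert traj.conservation_error() <= 1e-6
        assert np.all(np.diff(traj.D) >= -1e-9)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_months,IGF1_ng_ml,IL6_pg_ml,M,MD,D"

    def test_biomarkers_bounded_by_production_box(self):
        rng = np.random.default_rng(42)
        op = OutcomeParams(k_loss=0.0, k_gain=0.0, k_mort=1e-3,
                           k_longevity=0.01, k_extra=2.5)
        t = np.linspace(0.0, 500.0, 51)
        for _ in range(10):
            p = BiomarkerParams(
                kp_IGF1=10 ** rng.uniform(-1, 2), ks_IL6=10 ** rng.uniform(-3, 1),
                kd_IGF1=10 ** rng.uniform(-2, 0), kp_IL6=10 ** rng.uniform(-1, 2),
                ks_IGF1=10 ** rng.uniform(-4, 0), kd_IL6=10 ** rng.uniform(-2, 0),
            )
            x0 = rng.uniform(0, p.igf1_max)
            y0 = rng.uniform(0, p.il6_max)
            traj = simulate(StateVector(t=0.0, IGF1=x0, IL6=y0), p, op, t)
            assert traj.IGF1.max() <= p.igf1_max * (1 + 1e-8)
            assert traj.IL6.max() <= p.il6_max * (1 + 1e-8)
            assert min(traj.IGF1.min(), traj.IL6.min()) >= -1e-8

    def test_bad_grid_rejected(self, ref_outcome):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate(StateVector(t=0.0, IGF1=1.0, IL6=1.0), REF_BP, ref_outcome,
                     [0.0, 2.0, 1.0])


class TestSteadyStates:
    def test_uncoupled_system_has_single_stable_point(self):
        p = BiomarkerParams(kp_IGF1=8.0, ks_IL6=0.0, kd_IGF1=0.02,
                            kp_IL6=0.175, ks_IGF1=0.0, kd_IL6=0.007)
        states = find_biomarker_steady_states(p)
        assert len(states) == 1
        s = states[0]
        assert s.stability == "stable"
        assert s.IGF1_star == pytest.approx(400.0, rel=1e-9)
        assert s.IL6_star == pytest.approx(25.0, rel=1e-9)

    def test_symmetric_toggle_has_saddle_and_two_stable(self):
        states = find_biomarker_steady_states(SYM_BP)
        assert [s.stability for s in states] == ["stable", "saddle", "stable"]
        root = bisect_root(lambda x: 10 * x**3 + x - 1, 0.0, 1.0)
        saddle = states[1]
        assert saddle.IGF1_star == pytest.approx(root, abs=1e-9)
        assert saddle.IL6_star == pytest.approx(root, abs=1e-9)
        # saddle iff the off-diagonal inhibition product exceeds kd1*kd2
        eig = np.array(saddle.eigenvalues)
        assert eig.real.min() < 0 < eig.real.max()
        lo_state, hi_state = states[0], states[2]
        assert hi_state.IGF1_star == pytest.approx(lo_state.IL6_star, abs=1e-9)
        assert hi_state.IGF1_star > 0.85

    def test_residuals_below_root_tolerance(self):
        for p in (SYM_BP, REF_BP):
            for s in find_biomarker_steady_states(p):
                assert s.residual < 1e-9

    def test_stable_states_sorted_low_igf1_first(self):
        st_list = stable_states(find_biomarker_steady_states(REF_BP))
        assert len(st_list) == 2
        assert st_list[0].IGF1_star < st_list[1].IGF1_star


class TestClosedFormSurvival:
    def test_initial_condition(self):
        assert closed_form_survival(0.0, 2e-3, 0.015, M0=0.8) == 0.8

    def test_zero_longevity_limit(self):
        t = 120.0
        exact = 0.9 * math.exp(-2e-3 * t)
        assert closed_form_survival(t, 2e-3, 0.0, M0=0.9) == pytest.approx(exact)
        near = closed_form_survival(t, 2e-3, 1e-12, M0=0.9)
        assert near == pytest.approx(exact, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            closed_form_survival(-1.0, 2e-3, 0.015)


def test_parameter_json_roundtrip(tmp_path, ref_outcome):
    path = tmp_path / "params.json"
    save_parameters(path, REF_BP, ref_outcome, extra={"note": "test"})
    bp, op = load_parameters(path)
    assert bp == REF_BP
    assert op == ref_outcome
    import json

    doc = json.loads(path.read_text())
    assert doc["units"]["kp_IGF1"] == "ng/ml/month"


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(kp_IGF1=-1.0, ks_IL6=0.3, kd_IGF1=0.02, kp_IL6=0.2, ks_IGF1=5e-4,
             kd_IL6=0.007),
        dict(kp_IGF1=8.0, ks_IL6=0.3, kd_IGF1=0.0, kp_IL6=0.2, ks_IGF1=5e-4,
             kd_IL6=0.007),
        dict(kp_IGF1=8.0, ks_IL6=0.3, kd_IGF1=0.02, kp_IL6=0.2, ks_IGF1=5e-4,
             kd_IL6=0.007, hill_n=0),
    ],
)
def test_invalid_biomarker_params_rejected(kwargs):
    with pytest.raises(ValueError):
        BiomarkerParams(**kwargs)


def test_k_extra_below_one_rejected():
    with pytest.raises(ValueError, match="k_extra"):
        OutcomeParams(k_loss=0.01, k_gain=1e-3, k_mort=1e-3, k_longevity=0.01,
                      k_extra=0.5)
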