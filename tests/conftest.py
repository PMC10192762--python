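"""Shared fixtures.

The expensive full-calibration result is computed once per session and
shared between the calibration, outcomes, bistability and acceptance
tests; everything is seeded, so the session is deterministic.
"""

import numpy as np
import pytest

from frailswitch import (
    BiomarkerParams,
    OutcomeParams,
    calibrate_all,
    find_separatrix,
    generate_all,
)

#: round-number bistable reference set in physiological units, used as
#: ground truth for recovery tests and as a stand-in for a calibrated
#: model where the real calibration would be overkill
REF_BP = BiomarkerParams(
    kp_IGF1=400.0 * 0.02, ks_IL6=0.3, kd_IGF1=0.02,
    kp_IL6=25.0 * 0.007, ks_IGF1=5e-4, kd_IL6=0.007,
)

#: the classic symmetric toggle (both species identical, strong mutual
#: inhibition) whose separatrix is the diagonal by symmetry
SYM_BP = BiomarkerParams(
    kp_IGF1=1.0, ks_IL6=10.0, kd_IGF1=1.0,
    kp_IL6=1.0, ks_IGF1=10.0, kd_IL6=1.0,
)

#: outcome rates in the regime where the 60-month cohort data identify
#: every parameter (compartment exchange on a ~2-year timescale)
REF_OP = OutcomeParams(
    k_loss=0.012, k_gain=6e-4, k_mort=0.002, k_longevity=0.0155, k_extra=2.5
)


@pytest.fixture(scope="session")
def ref_params() -> BiomarkerParams:
    return REF_BP


@pytest.fixture(scope="session")
def sym_params() -> BiomarkerParams:
    return SYM_BP


@pytest.fixture(scope="session")
def ref_outcome() -> OutcomeParams:
    return REF_OP


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study conditions (population, trend, cohorts)."""
    return generate_all(seed=1)


@pytest.fixture(scope="session")
def calibrated(bundle):
    """Full literature-constraint calibration on the default fixtures."""
    return calibrate_all(bundle.trend, bundle.outcome_fixtures, seed=1)


@pytest.fixture(scope="session")
def separatrix_cal(calibrated):
    return find_separatrix(calibrated.biomarker, n_lines=21)


def rel_err(a: float, b: float) -> float:
    return abs(a - b) / abs(b)
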