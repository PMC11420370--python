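import numpy as np
import pytest

from casecohort import RiskRequest, design_weights
from casecohort.simulate import (
    SimulationScenario,
    generate_cohort,
    sample_design,
    _mask_phase2,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240906)


def make_case_cohort(n=60, pY=0.35, seed=7, sample_seed=11, frac=0.6, missing=0.0,
                     missing_seed=3):
    """Small simulated stratified case-cohort frame with design weights.

    Returns (frame, weights, m).  ``missing`` > 0 knocks out phase-two
    covariates for a fraction of the phase-two sample (phase three).
    """
    scn = SimulationScenario(n=n, pY=pY, reps=1, base_seed=seed)
    cohort = generate_cohort(scn, seed)
    m = np.maximum((cohort.stratum_sizes() * frac).astype(int), 2)
    xi = sample_design(cohort, m, sample_seed)
    frame = _mask_phase2(cohort, xi)
    if missing > 0:
        r = np.random.default_rng(missing_seed)
        v = np.zeros(frame.n, dtype=int)
        ph2 = frame.xi == 1
        v[ph2] = (r.random(ph2.sum()) > missing).astype(int)
        frame.v = v.astype(np.int8)
        frame.covariates[v == 0, 0] = np.nan
        frame.covariates[v == 0, 2] = np.nan
    weights = design_weights(frame, m)
    return frame, weights, m


@pytest.fixture
def small_cc():
    return make_case_cohort()


@pytest.fixture
def medium_cc():
    return make_case_cohort(n=400, pY=0.15, seed=5, sample_seed=13, frac=0.35)


@pytest.fixture
def risk_request():
    return RiskRequest(0.5, 8.0, [[1.0, 0.0, 0.5], [-0.5, 1.0, 0.0]])
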