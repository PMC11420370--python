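import numpy as np
import pytest

from casecohort import RiskRequest, design_weights
from casecohort.cox_engine import solve_weighted_score
from casecohort.data_model import ValidationError, build_frame
from casecohort.influence import influence_design
from casecohort.phase3 import (
    estimate_phase3_weights,
    estimate_threephase,
    handle_undefined_times,
    influence_threephase,
    phase3_weights_known,
    variance_threephase,
)
from casecohort.variance import pair_rule, variance_twophase
from casecohort.simulate import (
    SimulationScenario,
    generate_cohort,
    sample_design,
    _mask_phase2,
)

from _oracles import central_difference, threephase_estimates
from conftest import make_case_cohort


@pytest.fixture(scope="module")
def missing_cc():
    frame, weights, m = make_case_cohort(
        n=60, pY=0.35, seed=2, sample_seed=5, frac=0.7, missing=0.2
    )
    req = RiskRequest(0.5, 8.0, [[1.0, 0.0, 0.5]])
    p3 = estimate_phase3_weights(frame)
    fit = estimate_threephase(frame, weights, p3, req)
    sets = influence_threephase(frame, weights, p3, fit, req)
    return frame, weights, req, p3, fit, sets


class TestWeights:
    def test_ratio_example(self):
        n = 12
        ev = np.array([1, 1] + [0] * 10)
        xi = np.ones(n, dtype=int)
        v = np.array([1, 1] + [1] * 8 + [0] * 2)
        frame = build_frame(
            subject_id=np.arange(n), stratum=np.zeros(n, dtype=int),
            entry_time=np.zeros(n), exit_time=np.arange(1, n + 1, dtype=float),
            event=ev, xi=xi, v=v,
            covariates=np.where(v[:, None] == 1, 0.0, np.nan),
        )
        p3 = estimate_phase3_weights(frame)
        noncase = frame.event == 0
        np.testing.assert_allclose(p3.w3[noncase], 10 / 8)
        np.testing.assert_allclose(p3.sigma3[noncase], 0.8 * 0.2)
        np.testing.assert_allclose(p3.w3[~noncase], 1.0)
        np.testing.assert_allclose(p3.sigma3[~noncase], 0.0)
        # estimating-equation balance per stratum: sum xi (1 - V w3) = 0
        for s in range(len(p3.n2)):
            sel = p3.strata3 == s
            bal = (frame.xi[sel] * (1 - frame.v[sel] * p3.w3[sel])).sum()
            assert abs(bal) <= 1e-10

    def test_no_missingness_unit_weights(self, small_cc):
        frame, weights, _ = small_cc
        p3 = estimate_phase3_weights(frame)
        np.testing.assert_allclose(p3.w3, 1.0)
        np.testing.assert_allclose(p3.sigma3, 0.0)

    def test_empty_stratum_rejected(self):
        n = 6
        ev = np.array([1, 0, 0, 0, 0, 0])
        v = np.array([1, 0, 0, 0, 0, 0])
        frame = build_frame(
            subject_id=np.arange(n), stratum=np.zeros(n, dtype=int),
            entry_time=np.zeros(n), exit_time=np.arange(1, n + 1, dtype=float),
            event=ev, xi=np.ones(n, dtype=int), v=v,
            covariates=np.where(v[:, None] == 1, 0.0, np.nan),
        )
        with pytest.raises(ValidationError, match="no complete data"):
            estimate_phase3_weights(frame)

    def test_known_probabilities_path(self, missing_cc):
        frame, weights, req, p3, fit, sets = missing_cc
        probs = 1.0 / p3.w3
        p3k = phase3_weights_known(frame, probs)
        np.testing.assert_allclose(p3k.w3, p3.w3)
        np.testing.assert_allclose(p3k.sigma3, p3.sigma3)
        assert p3k.known


class TestEstimate:
    def test_v_equal_one_reduces_to_twophase(self, small_cc):
        frame, weights, _ = small_cc
        req = RiskRequest(0.5, 8.0, [[1.0, 0.0, 0.5]])
        p3 = estimate_phase3_weights(frame)
        fit3 = estimate_threephase(frame, weights, p3, req)
        xi = (frame.xi == 1).astype(float)
        fit2 = solve_weighted_score(frame, weights.combined, xi)
        np.testing.assert_allclose(fit3.beta, fit2.beta, atol=1e-12)
        np.testing.assert_allclose(fit3.jumps, fit2.jumps, atol=1e-14)

    def test_incomplete_noncase_not_in_risk_sets(self, missing_cc):
        frame, weights, req, p3, fit, sets = missing_cc
        assert np.all(fit.include[(frame.v == 0)] == 0)

    def test_mcar_estimates_unbiased(self):
        """20% MCAR missingness: bias of beta within 3 MC SE over replicates."""
        scn = SimulationScenario(n=1500, pY=0.1, reps=1, base_seed=0)
        betas = []
        rng = np.random.default_rng(5)
        for r in range(150):
            cohort = generate_cohort(scn, 600 + r)
            m = np.maximum((cohort.stratum_sizes() * 0.25).astype(int), 2)
            xi = sample_design(cohort, m, 4000 + r)
            frame = _mask_phase2(cohort, xi)
            v = np.zeros(frame.n, dtype=int)
            ph2 = frame.xi == 1
            v[ph2] = (rng.random(ph2.sum()) > 0.2).astype(int)
            frame.v = v.astype(np.int8)
            frame.covariates[v == 0, 0] = np.nan
            frame.covariates[v == 0, 2] = np.nan
            w = design_weights(frame, m)
            p3 = estimate_phase3_weights(frame)
            fit = estimate_threephase(frame, w, p3)
            betas.append(fit.beta)
        betas = np.asarray(betas)
        bias = betas.mean(axis=0) - np.asarray(scn.beta)
        mc_se = betas.std(axis=0, ddof=1) / np.sqrt(len(betas))
        assert np.all(np.abs(bias) <= 3 * mc_se)


class TestUndefinedTimes:
    def _toy(self):
        # one isolated event from a V=0 case at t=5 when nobody complete is at risk
        n = 8
        exit_t = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0])
        ev = np.array([1, 0, 0, 0, 1, 0, 0, 1])
        v = np.array([1, 1, 1, 1, 1, 1, 1, 0])
        X = np.where(
            v[:, None] == 1,
            np.array([0.5, -0.3, 0.2, 0.9, -0.7, 0.1, 0.4, 0.0])[:, None],
            np.nan,
        )
        return build_frame(
            subject_id=np.arange(n), stratum=np.zeros(n, dtype=int),
            entry_time=np.zeros(n), exit_time=exit_t, event=ev,
            xi=np.ones(n, dtype=int), v=v, covariates=X,
        )

    def test_no_such_times_grid_unchanged(self, small_cc):
        frame, weights, _ = small_cc
        p3 = estimate_phase3_weights(frame)
        grid, dropped = handle_undefined_times(frame, p3)
        assert dropped == 0
        assert len(grid.times) == len(np.unique(frame.exit_time[frame.event == 1]))

    def test_isolated_missing_case_time_dropped(self):
        frame = self._toy()
        p3 = estimate_phase3_weights(frame)
        with pytest.warns(UserWarning, match="dropping 1 event time"):
            grid, dropped = handle_undefined_times(frame, p3)
        assert dropped == 1
        assert 5.0 not in grid.times
        assert len(grid.times) == 2

    def test_dropped_count_reported_on_fit(self):
        frame = self._toy()
        w = design_weights(frame, [5])
        p3 = estimate_phase3_weights(frame)
        with pytest.warns(UserWarning):
            fit = estimate_threephase(frame, w, p3)
        assert fit.dropped_times == 1


class TestInfluence:
    def test_matches_perturbation_oracle(self, missing_cc):
        frame, weights, req, p3, fit, sets = missing_cc
        fn = lambda mass: threephase_estimates(
            frame, weights.w2, p3.strata3, len(p3.n2), req, mass
        )
        rng = np.random.default_rng(1)
        idx = list(rng.choice(frame.n, 25, replace=False))
        for i in idx:
            fd_beta, fd_lam, fd_pi = central_difference(fn, frame.n, i)
            np.testing.assert_allclose(sets["beta"].delta[i], fd_beta, atol=1e-3)
            np.testing.assert_allclose(sets["cumhaz"].delta[i, 0], fd_lam, atol=1e-3)
            np.testing.assert_allclose(
                sets["pure_risk"].delta[i, 0], fd_pi[0], atol=1e-3
            )

    def test_incomplete_phase2_subject_has_influence(self, missing_cc):
        frame, weights, req, p3, fit, sets = missing_cc
        sel = (frame.xi == 1) & (frame.v == 0)
        assert sel.any()
        s = sets["beta"]
        assert np.abs(s.delta[sel]).max() > 0
        assert np.abs(s.if3[sel]).max() == 0.0

    def test_v_equal_one_deviates_match_twophase(self, small_cc):
        frame, weights, _ = small_cc
        req = RiskRequest(0.5, 8.0, [[1.0, 0.0, 0.5]])
        p3 = estimate_phase3_weights(frame)
        fit3 = estimate_threephase(frame, weights, p3, req)
        sets3 = influence_threephase(frame, weights, p3, fit3, req)
        xi = (frame.xi == 1).astype(float)
        fit2 = solve_weighted_score(frame, weights.combined, xi)
        sets2 = influence_design(frame, weights.combined, fit2, req)
        for name in sets2:
            np.testing.assert_allclose(
                sets3[name].delta, sets2[name].delta, atol=1e-12
            )


class TestVariance:
    def test_v_equal_one_collapses_to_twophase(self, small_cc):
        frame, weights, _ = small_cc
        req = RiskRequest(0.5, 8.0, [[1.0, 0.0, 0.5]])
        p3 = estimate_phase3_weights(frame)
        fit3 = estimate_threephase(frame, weights, p3, req)
        sets3 = influence_threephase(frame, weights, p3, fit3, req)
        xi = (frame.xi == 1).astype(float)
        fit2 = solve_weighted_score(frame, weights.combined, xi)
        sets2 = influence_design(frame, weights.combined, fit2, req)
        rule = pair_rule(frame, weights)
        for name in sets2:
            rep3 = variance_threephase(sets3[name], weights, rule, p3, frame)
            rep2 = variance_twophase(sets2[name], weights.combined, rule, xi=xi)
            np.testing.assert_allclose(rep3.total, rep2.total, atol=1e-12)

    def test_grouped_equals_naive_pairs(self, missing_cc):
        frame, weights, req, p3, fit, sets = missing_cc
        rule = pair_rule(frame, weights)
        fast = variance_threephase(sets["beta"], weights, rule, p3, frame)
        slow = variance_threephase(
            sets["beta"], weights, rule, p3, frame, naive=True
        )
        np.testing.assert_allclose(fast.total, slow.total, atol=1e-10)

    def test_invariant_to_stratum3_relabeling(self, missing_cc):
        frame, weights, req, p3, fit, sets = missing_cc
        rule = pair_rule(frame, weights)
        rep = variance_threephase(sets["beta"], weights, rule, p3, frame)
        labels = np.where(frame.event == 1, "zzz_case", "aaa_noncase")
        p3b = estimate_phase3_weights(frame, labels)
        fitb = estimate_threephase(frame, weights, p3b, req)
        setsb = influence_threephase(frame, weights, p3b, fitb, req)
        repb = variance_threephase(setsb["beta"], weights, rule, p3b, frame)
        np.testing.assert_allclose(repb.total, rep.total, atol=1e-12)

    def test_threephase_variance_exceeds_twophase_on_matched_replicates(self):
        """Extra phase adds variance: median over replicates of the
        three-phase total minus the matched two-phase total is >= 0."""
        scn = SimulationScenario(n=1200, pY=0.12, reps=1, base_seed=0)
        rng = np.random.default_rng(2)
        excess = []
        for r in range(25):
            cohort = generate_cohort(scn, 900 + r)
            m = np.maximum((cohort.stratum_sizes() * 0.3).astype(int), 2)
            xi = sample_design(cohort, m, 7000 + r)
            full = _mask_phase2(cohort, xi)
            w = design_weights(full, m)
            xif = (full.xi == 1).astype(float)
            fit2 = solve_weighted_score(full, w.combined, xif)
            sets2 = influence_design(full, w.combined, fit2)
            rule = pair_rule(full, w)
            rep2 = variance_twophase(sets2["beta"], w.combined, rule, xi=xif)
            frame = full.copy()
            v = np.zeros(frame.n, dtype=int)
            ph2 = frame.xi == 1
            v[ph2] = (rng.random(ph2.sum()) > 0.2).astype(int)
            frame.v = v.astype(np.int8)
            frame.covariates[v == 0, 0] = np.nan
            frame.covariates[v == 0, 2] = np.nan
            p3 = estimate_phase3_weights(frame)
            fit3 = estimate_threephase(frame, w, p3)
            sets3 = influence_threephase(frame, w, p3, fit3)
            rep3 = variance_threephase(sets3["beta"], w, rule, p3, frame)
            excess.append(np.diag(rep3.total) - np.diag(rep2.total))
        assert np.all(np.median(excess, axis=0) >= 0)

    def test_coverage_under_mcar(self):
        """95% CIs from the three-phase variance cover the truth at nominal
        level (3-sigma binomial band at this replicate count)."""
        scn = SimulationScenario(n=1500, pY=0.1, reps=1, base_seed=0)
        rng = np.random.default_rng(9)
        B = 250
        cover = np.zeros(3)
        for r in range(B):
            cohort = generate_cohort(scn, 2000 + r)
            m = np.maximum((cohort.stratum_sizes() * 0.25).astype(int), 2)
            xi = sample_design(cohort, m, 8000 + r)
            frame = _mask_phase2(cohort, xi)
            v = np.zeros(frame.n, dtype=int)
            ph2 = frame.xi == 1
            v[ph2] = (rng.random(ph2.sum()) > 0.2).astype(int)
            frame.v = v.astype(np.int8)
            frame.covariates[v == 0, 0] = np.nan
            frame.covariates[v == 0, 2] = np.nan
            w = design_weights(frame, m)
            p3 = estimate_phase3_weights(frame)
            fit = estimate_threephase(frame, w, p3)
            sets = influence_threephase(frame, w, p3, fit)
            rule = pair_rule(frame, w)
            rep = variance_threephase(sets["beta"], w, rule, p3, frame)
            se = np.sqrt(np.diag(rep.total))
            z = 1.959963984540054
            truth = np.asarray(scn.beta)
            cover += (np.abs(fit.beta - truth) <= z * se).astype(float)
        cover /= B
        half = 3 * np.sqrt(0.95 * 0.05 / B)
        assert np.all(np.abs(cover - 0.95) <= half), cover
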