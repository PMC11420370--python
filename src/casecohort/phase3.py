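"""Missing phase-two covariates treated as a third sampling phase.

Missingness indicators ``V`` are Bernoulli within phase-three strata; the
per-stratum weights are estimated as (phase-two count)/(complete count),
estimation proceeds with inclusion ``xi V`` and combined weights
``w2 * w3``, and the variance decomposes into superpopulation, phase-two
and phase-three terms.  The influence of the estimated phase-three weights
is carried in the phase-two part of the deviates, which reduces the
phase-three variance term relative to treating the weights as known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import CohortFrame, DesignWeights, RiskRequest, ValidationError
from .cox_engine import CoxFit, _masked_covariates, build_grid, solve_weighted_score
from .influence import InfluenceSet, _as2d, risk_partials, score_residuals
from .variance import PairRule, VarianceReport

__all__ = [
    "Phase3Weights",
    "estimate_phase3_weights",
    "phase3_weights_known",
    "handle_undefined_times",
    "estimate_threephase",
    "influence_threephase",
    "variance_threephase",
]


@dataclass
class Phase3Weights:
    gamma: np.ndarray | None     # (J3,) log weights; None when supplied
    strata3: np.ndarray          # (n,) codes 0..J3-1
    strata3_labels: np.ndarray
    w3: np.ndarray               # (n,) estimated or known weight
    sigma3: np.ndarray           # (n,) estimated var(V)
    n2: np.ndarray               # (J3,) phase-two counts per stratum
    known: bool = False


def _codes(labels):
    uniq = np.unique(np.asarray(labels))
    return np.searchsorted(uniq, labels).astype(np.intp), uniq


def estimate_phase3_weights(frame: CohortFrame, strata3=None) -> Phase3Weights:
    """Closed-form per-stratum ratio weights (count xi)/(count xi V).

    Default phase-three strata are case status.  Solves the estimating
    equation sum_i { xi B_i - exp(gamma'B_i) xi V B_i } = 0 exactly.
    """
    if (frame.v == 0).any() and ((frame.v == 1) & (frame.xi == 0)).any():
        raise ValidationError("V=1 outside the phase-two sample")
    if strata3 is None:
        strata3 = np.where(frame.event == 1, "case", "noncase")
    codes, labels = _codes(strata3)
    J3 = len(labels)
    xi = frame.xi == 1
    n2 = np.bincount(codes[xi], minlength=J3).astype(float)
    n3 = np.bincount(codes[xi & (frame.v == 1)], minlength=J3).astype(float)
    empty = (n2 > 0) & (n3 == 0)
    if empty.any():
        raise ValidationError(
            f"phase-three strata with phase-two members but no complete data: "
            f"{list(labels[empty])}"
        )
    ratio = np.divide(n2, n3, out=np.ones(J3), where=n3 > 0)
    w3 = ratio[codes]
    sigma3 = (1.0 / w3) * (1.0 - 1.0 / w3)
    gamma = np.log(ratio)
    return Phase3Weights(
        gamma=gamma, strata3=codes, strata3_labels=labels, w3=w3, sigma3=sigma3,
        n2=n2, known=False,
    )


def phase3_weights_known(frame: CohortFrame, probabilities, strata3=None) -> Phase3Weights:
    """Wrap known phase-three sampling probabilities in the same machinery."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("phase-three probabilities must lie in (0, 1]")
    if strata3 is None:
        strata3 = np.where(frame.event == 1, "case", "noncase")
    codes, labels = _codes(strata3)
    xi = frame.xi == 1
    n2 = np.bincount(codes[xi], minlength=len(labels)).astype(float)
    return Phase3Weights(
        gamma=None, strata3=codes, strata3_labels=labels, w3=1.0 / p,
        sigma3=p * (1.0 - p), n2=n2, known=True,
    )


def handle_undefined_times(frame: CohortFrame, p3: Phase3Weights):
    """Event times with no phase-three subject at risk are dropped and counted.

    Such times arise when a case with missing covariates fails while nobody
    with complete data is at risk; they are removed from all integrals.
    Returns (grid restricted to kept times, number dropped).
    """
    grid = build_grid(frame)
    include = ((frame.xi == 1) & (frame.v == 1)).astype(float)
    ok = (grid.at_risk * include[:, None]).sum(axis=0) > 0
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(
            f"dropping {dropped} event time(s) with empty phase-three risk sets"
        )
        grid = build_grid(frame, keep=ok)
    return grid, dropped


def estimate_threephase(
    frame: CohortFrame,
    weights: DesignWeights,
    p3: Phase3Weights,
    request: RiskRequest | None = None,
) -> CoxFit:
    """Three-phase fit: inclusion xi V, weights w2 * w3, unweighted Breslow
    numerator restricted to defined event times."""
    grid, dropped = handle_undefined_times(frame, p3)
    include = ((frame.xi == 1) & (frame.v == 1)).astype(float)
    wt = weights.w2 * p3.w3
    fit = solve_weighted_score(
        frame, wt, include, grid=grid, weights_used="phase3",
    )
    fit.dropped_times = dropped  # type: ignore[attr-defined]
    if request is not None:
        from .cox_engine import pure_risk

        fit.pure_risks = pure_risk(fit, request)  # type: ignore[attr-defined]
    return fit


def influence_threephase(
    frame: CohortFrame,
    weights: DesignWeights,
    p3: Phase3Weights,
    fit: CoxFit,
    request: RiskRequest | None = None,
    log_risk: bool = True,
) -> dict[str, InfluenceSet]:
    """Phase-two and phase-three influences for the three-phase estimates.

    Total deviates are ``Delta = xi IF2 + xi V w3 IF3``.  The phase-two part
    carries each phase-two subject's contribution to the estimated
    phase-three weights (a per-stratum centering of the weighted score
    residuals); the phase-three part holds the complete-data residual net of
    that centering.
    """
    xi = (frame.xi == 1).astype(float)
    inc = fit.include                      # xi V
    X = _masked_covariates(frame, inc)
    n = frame.n
    wt = fit.weights                       # w2 * w3
    s3 = p3.strata3
    J3 = len(p3.n2)
    n2 = p3.n2

    d = score_residuals(fit, X)            # zero outside phase three
    # D columns: per phase-three stratum, sum of included w-tilde d over n2
    wd = (inc * wt)[:, None] * d
    D = np.zeros((d.shape[1], J3))
    for s in range(J3):
        if n2[s] > 0:
            D[:, s] = wd[s3 == s].sum(axis=0) / n2[s]
    DB = D[:, s3].T                        # (n, p)
    if2b = np.linalg.solve(fit.info, DB.T).T
    if3b = np.linalg.solve(fit.info, (weights.w2[:, None] * d - DB).T).T
    if3b[inc == 0] = 0.0

    def pack(name, f2, f3):
        f2, f3 = _as2d(f2), _as2d(f3)
        delta = xi[:, None] * f2 + (inc * p3.w3)[:, None] * f3
        return InfluenceSet(name, f2, delta, if3=f3)

    out = {"beta": pack("beta", if2b, if3b)}
    if request is None:
        return out

    sel = (fit.event_times > request.tau1) & (fit.event_times <= request.tau2)
    e = inc * np.exp(np.clip(X @ fit.beta, -700, 700))
    if sel.any():
        c = fit.jumps[sel] / fit.s0[sel]
        own = np.zeros(n)
        has = fit.grid.event_col >= 0
        in_win = has & sel[np.clip(fit.grid.event_col, 0, None)]
        own[in_win] = 1.0 / fit.s0[fit.grid.event_col[in_win]]
        G0 = fit.grid.at_risk[:, sel] @ c
        drift = fit.s1[sel].T @ c          # (p,)
        # per phase-three stratum: sum_k c_k S0B_k(s) / n2_s
        r = inc * wt * np.exp(np.clip(X @ fit.beta, -700, 700))
        contrib = r * G0                   # sum_k sel c_k Y_ik r_i
        vB = np.zeros(J3)
        for s in range(J3):
            if n2[s] > 0:
                vB[s] = contrib[s3 == s].sum() / n2[s]
        hB = vB[s3]                        # (n,)
        if2L = own - if2b @ drift - hB
        if3L = -(weights.w2 * e * G0) - if3b @ drift + hB
        if3L[inc == 0] = 0.0
    else:
        if2L = np.zeros(n)
        if3L = np.zeros(n)
    out["cumhaz"] = pack("cumhaz", if2L, if3L)

    pi, dbeta, dlam_partial = risk_partials(fit, request)
    if2p = if2b @ dbeta.T + if2L[:, None] * dlam_partial[None, :]
    if3p = if3b @ dbeta.T + if3L[:, None] * dlam_partial[None, :]
    out["pure_risk"] = pack("pure_risk", if2p, if3p)
    if log_risk:
        if np.any(pi <= 0):
            raise ValidationError("log pure risk undefined: estimated risk is 0")
        out["log_pure_risk"] = pack(
            "log_pure_risk", if2p / pi[None, :], if3p / pi[None, :]
        )
    return out


def variance_threephase(
    infl: InfluenceSet,
    weights: DesignWeights,
    rule: PairRule,
    p3: Phase3Weights,
    frame: CohortFrame,
    naive: bool = False,
) -> VarianceReport:
    """Four-block three-phase variance estimate.

    Blocks: superpopulation (1/w2 factors), phase-two diagonal (sigma2 w2),
    phase-two off-diagonal pairs (joint weights/covariances on the total
    phase-2+3 deviates), and the phase-three block (sigma3)."""
    if infl.if3 is None:
        raise ValidationError("three-phase variance requires phase-three influences")
    xi = (frame.xi == 1).astype(float)
    inc = xi * (frame.v == 1)
    w2 = weights.w2
    w3 = p3.w3
    if2, if3 = infl.if2, infl.if3
    n = frame.n
    b = inc * w3                          # xi V w3

    # symmetric accumulation helper: sum_i c_i {a_i u2u2' + b_i (u2u3'+u3u2') + b_i u3u3'}
    def block(c):
        t = np.einsum("i,ij,ik->jk", c * xi, if2, if2)
        cr = np.einsum("i,ij,ik->jk", c * b, if2, if3)
        t += cr + cr.T
        t += np.einsum("i,ij,ik->jk", c * b, if3, if3)
        return t

    block1 = (n / (n - 1.0)) * block(1.0 / w2)
    block2 = block(rule.sigma_diag * w2)
    # off-diagonal pairs on u_i = xi IF2 + xi V w3 IF3, non-case pairs only
    u = xi[:, None] * if2 + b[:, None] * if3
    d = u.shape[1]
    block3 = np.zeros((d, d))
    if rule.mode == "without_replacement":
        if naive:
            idx = np.where((xi > 0) & rule.noncase)[0]
            for i in idx:
                for k in idx:
                    if i == k or rule.stratum[i] != rule.stratum[k]:
                        continue
                    block3 += (
                        rule.w_pair[rule.stratum[i]]
                        * rule.sigma_pair[rule.stratum[i]]
                        * np.outer(u[i], u[k])
                    )
        else:
            for j in range(len(rule.w_pair)):
                s = (rule.stratum == j) & rule.noncase & (xi > 0)
                if not s.any():
                    continue
                S = u[s].sum(axis=0)
                Q = u[s].T @ u[s]
                block3 += rule.w_pair[j] * rule.sigma_pair[j] * (np.outer(S, S) - Q)
    block4 = np.einsum(
        "i,ij,ik->jk", p3.sigma3 * w3 * inc * w3 * w3, if3, if3
    )
    total = block1 + block2 + block3 + block4
    delta = infl.delta
    robust = delta.T @ delta
    return VarianceReport(
        total=total,
        robust=robust,
        phase2_component=block2 + block3,
        difference=robust - total,
        method="threephase",
    )
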