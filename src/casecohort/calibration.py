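"""Survey-weight calibration (raking) for case-cohort estimation.

Auxiliary variables built from cohort-wide information are used to perturb
the design weights multiplicatively, ``w* = w exp(eta'A)``, so that weighted
phase-two totals of the auxiliaries match their cohort totals.  Estimation
then proceeds with ``w*`` in the risk-set sums and score, keeping the
unweighted cohort event counts in the Breslow numerator.  Influences split
into a phase-one part (defined for every cohort member, capturing each
subject's effect on the calibration constraints) and a phase-two part that
behaves as a weighted residual from regressing on the auxiliaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import CohortFrame, DesignWeights, RiskRequest, ValidationError
from .cox_engine import CoxFit, _masked_covariates, build_grid, solve_weighted_score
from .influence import InfluenceSet, _as2d, risk_partials, score_residuals
from .variance import PairRule, VarianceReport, _phase2_blocks, _phase2_naive

__all__ = [
    "AuxiliaryMatrix",
    "CalibratedWeights",
    "CalibrationError",
    "impute_phase2",
    "build_auxiliary",
    "calibrate_weights",
    "estimate_calibrated",
    "influence_calibrated",
    "variance_calibrated",
]

WEIGHT_EXPLOSION_BOUND = 100.0


class CalibrationError(RuntimeError):
    pass


@dataclass
class AuxiliaryMatrix:
    """Cohort-wide auxiliary variables, grouped into blocks.

    block (i): influences on the log-relative hazard from a full-cohort Cox
    fit on imputed covariates; block (ii): follow-up time in the risk
    interval times the imputed relative hazard; block (iii): the constant 1.
    """

    matrix: np.ndarray           # (n, q)
    block_i: slice
    block_ii: slice | None
    block_iii: slice
    meta: dict = field(default_factory=dict)

    @property
    def q(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CalibratedWeights:
    eta: np.ndarray
    wstar: np.ndarray
    residual_norm: float
    aux: AuxiliaryMatrix | None = None


def _design_matrix(frame: CohortFrame, predictors: list[str]) -> np.ndarray:
    """Column-bind named phase-one variables (proxies or phase-one covariates)
    with an intercept."""
    cols = [np.ones(frame.n)]
    for name in predictors:
        if name in frame.proxy_names:
            col = frame.proxies[:, frame.proxy_names.index(name)]
        elif name in frame.covariate_names:
            col = frame.covariates[:, frame.covariate_names.index(name)]
        else:
            raise ValidationError(f"unknown predictor column {name!r}")
        if np.isnan(col).any():
            raise ValidationError(
                f"predictor {name!r} is missing for some cohort members"
            )
        cols.append(col)
    return np.column_stack(cols)


def impute_phase2(
    frame: CohortFrame, weights: DesignWeights, proxy_spec: dict[str, list[str]]
) -> np.ndarray:
    """Weighted-least-squares imputation of phase-two covariates, cohort-wide.

    Each phase-two covariate named in ``proxy_spec`` is regressed on its
    phase-one predictors within the phase-two sample using the design
    weights; fitted values replace the column for ALL cohort members,
    including those with measured values.  Other columns pass through.
    """
    X = frame.covariates.copy()
    sel = frame.xi == 1
    w = weights.combined[sel]
    for cov, predictors in proxy_spec.items():
        if cov not in frame.covariate_names:
            raise ValidationError(f"unknown covariate {cov!r} in imputation spec")
        j = frame.covariate_names.index(cov)
        Z = _design_matrix(frame, predictors)
        y = frame.covariates[sel, j]
        if np.isnan(y).any():
            raise ValidationError(f"covariate {cov!r} missing inside phase two")
        Zs = Z[sel] * np.sqrt(w)[:, None]
        if np.linalg.matrix_rank(Zs) < Z.shape[1]:
            raise ValidationError(
                f"collinear predictors {predictors} for imputing {cov!r}"
            )
        coef, *_ = np.linalg.lstsq(Zs, y * np.sqrt(w), rcond=None)
        X[:, j] = Z @ coef
    return X


def calibrate_weights(
    frame: CohortFrame,
    weights,
    aux: AuxiliaryMatrix,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> CalibratedWeights:
    """Raking: solve sum_i { xi_i w_i exp(eta'A_i) A_i - A_i } = 0 by Newton
    iteration with step-halving."""
    w = weights.combined if isinstance(weights, DesignWeights) else np.asarray(weights, float)
    A = aux.matrix
    xi = (frame.xi == 1).astype(float)
    if aux.q >= int(xi.sum()):
        raise CalibrationError("more auxiliary variables than phase-two subjects")
    target = A.sum(axis=0)
    eta = np.zeros(aux.q)

    def residual(e):
        ws = xi * w * np.exp(np.clip(A @ e, -200, 200))
        return ws @ A - target, ws

    g, ws = residual(eta)
    norm = np.abs(g).max()
    scale = max(1.0, np.abs(target).max())
    for it in range(max_iter):
        if norm <= tol * scale:
            break
        H = (ws[:, None] * A).T @ A
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise CalibrationError(f"singular calibration system: {exc}") from exc
        s = 1.0
        for _ in range(40):
            cand = eta - s * step
            gc, wsc = residual(cand)
            if np.abs(gc).max() < norm or s < 1e-8:
                break
            s /= 2
        eta, g, ws = cand, gc, wsc
        norm = np.abs(g).max()
    if norm > tol * scale:
        raise CalibrationError(
            f"raking did not converge: residual |g|_inf = {norm:.3e}"
        )
    wstar = w * np.exp(np.clip(A @ eta, -200, 200))
    ratio = np.max(wstar[xi > 0] / w[xi > 0])
    if ratio > WEIGHT_EXPLOSION_BOUND:
        raise CalibrationError(
            f"calibrated/design weight ratio {ratio:.1f} exceeds "
            f"{WEIGHT_EXPLOSION_BOUND}; reduce the auxiliary set"
        )
    return CalibratedWeights(eta=eta, wstar=wstar, residual_norm=float(norm), aux=aux)


def _prune_collinear(A: np.ndarray, keep_last: bool = True) -> tuple[np.ndarray, list[int]]:
    """Drop columns until the cross-product is well conditioned (no ridge)."""
    cols = list(range(A.shape[1]))
    while len(cols) > 1:
        sub = A[:, cols]
        s = np.linalg.svd(sub, compute_uv=False)
        if s[-1] > 1e-9 * s[0]:
            break
        # drop the non-constant column most aligned with the null space
        _, _, vt = np.linalg.svd(sub)
        order = np.argsort(-np.abs(vt[-1]))
        drop = next(c for c in order if not keep_last or cols[c] != cols[-1])
        warnings.warn(f"pruning collinear auxiliary column {cols[drop]}")
        cols.pop(drop)
    return A[:, cols], cols


def build_auxiliary(
    frame: CohortFrame,
    weights: DesignWeights,
    imputed: np.ndarray,
    request: RiskRequest,
) -> AuxiliaryMatrix:
    """Auxiliary blocks (i) + (ii) + (iii) via the two-stage recipe.

    Stage one calibrates against (i)+(iii) only and fits the case-cohort
    model with those weights; the resulting log-relative hazards form the
    imputed relative hazard in block (ii).
    """
    imputed = np.asarray(imputed, dtype=float)
    if np.isnan(imputed).any():
        raise ValidationError("imputed covariates must be available cohort-wide")
    n, p = imputed.shape
    # block (i): full-cohort fit on imputed covariates, unit weights
    imp_frame = frame.copy()
    imp_frame.covariates = imputed
    imp_frame.xi = np.ones(n, dtype=np.int8)
    imp_frame.v = np.ones(n, dtype=np.int8)
    ones = np.ones(n)
    fit_full = solve_weighted_score(imp_frame, ones, ones, weights_used="imputed_cohort")
    from .influence import if2_beta  # local import to avoid cycle at module load

    block_i = if2_beta(imp_frame, ones, fit_full)
    # stage one: calibrate on (i) + (iii), fit with true phase-two covariates
    A1_raw = np.column_stack([block_i, ones])
    A1, kept = _prune_collinear(A1_raw)
    aux1 = AuxiliaryMatrix(
        matrix=A1, block_i=slice(0, A1.shape[1] - 1), block_ii=None,
        block_iii=slice(A1.shape[1] - 1, A1.shape[1]),
    )
    try:
        cal1 = calibrate_weights(frame, weights, aux1)
        fit1 = estimate_calibrated(frame, cal1, request=None)
        beta_stage1 = fit1.beta
    except (CalibrationError, ValidationError) as exc:
        raise CalibrationError(f"stage-one calibration failed: {exc}") from exc
    # block (ii): time at risk in the interval times imputed relative hazard
    if frame.timescale == "age":
        start = np.maximum(frame.entry_time, request.tau1)
    else:
        start = np.full(n, request.tau1)
    time_in = np.maximum(
        0.0, np.minimum(frame.exit_time, request.tau2) - start
    )
    block_ii = time_in * np.exp(imputed @ beta_stage1)
    A_raw = np.column_stack([block_i, block_ii, ones])
    A, kept = _prune_collinear(A_raw)
    q = A.shape[1]
    return AuxiliaryMatrix(
        matrix=A,
        block_i=slice(0, q - 2),
        block_ii=slice(q - 2, q - 1),
        block_iii=slice(q - 1, q),
        meta={
            "stage1_beta": beta_stage1,
            "kept_columns": kept,
            "imputed_cohort_beta": fit_full.beta,
        },
    )


def estimate_calibrated(
    frame: CohortFrame, cal: CalibratedWeights, request: RiskRequest | None
):
    """Cox fit with calibrated weights in the risk sets and score; the Breslow
    numerator keeps the unweighted cohort event counts."""
    xi = (frame.xi == 1).astype(float)
    fit = solve_weighted_score(
        frame,
        cal.wstar,
        xi,
        dn_weights=xi * cal.wstar,
        weights_used="calibrated",
    )
    if request is not None:
        from .cox_engine import pure_risk

        fit.pure_risks = pure_risk(fit, request)  # type: ignore[attr-defined]
    return fit


def influence_calibrated(
    frame: CohortFrame,
    weights: DesignWeights,
    cal: CalibratedWeights,
    fit: CoxFit,
    request: RiskRequest | None = None,
    log_risk: bool = True,
) -> dict[str, InfluenceSet]:
    """Phase-one and phase-two influences under calibrated weights.

    The phase-one part is nonzero for every cohort member (each influences
    the calibration constraints through the auxiliary totals); the weighted
    phase-two parts are orthogonal to the auxiliary columns.
    """
    if cal.aux is None:
        raise ValidationError("CalibratedWeights must carry its auxiliary matrix")
    A = cal.aux.matrix
    xi = fit.include
    w = weights.combined
    wstar = cal.wstar
    X = _masked_covariates(frame, xi)
    n = frame.n

    d = score_residuals(fit, X)                       # (n, p), zero for xi=0
    xiws = xi * wstar
    H = (xiws[:, None] * A).T @ A
    Hinv = np.linalg.inv(H)
    C = ((xiws[:, None] * d).T @ A) @ Hinv            # (p, q)
    resid = d - A @ C.T                               # d_i - C A_i
    if1b = np.linalg.solve(fit.info, (A @ C.T).T).T   # (n, p), dense
    ratio = np.divide(wstar, w, out=np.zeros(n), where=w > 0)
    if2b = np.linalg.solve(fit.info, (ratio[:, None] * resid).T).T
    if2b[xi == 0] = 0.0

    xiw = (xi * w)[:, None]
    out = {
        "beta": InfluenceSet("beta", if2b, if1b + xiw * if2b, if1=if1b)
    }
    if request is None:
        return out

    sel = (fit.event_times > request.tau1) & (fit.event_times <= request.tau2)
    e = xi * np.exp(np.clip(X @ fit.beta, -700, 700))
    if sel.any():
        c = fit.jumps[sel] / fit.s0[sel]
        own = np.zeros(n)
        has = fit.grid.event_col >= 0
        in_win = has & sel[np.clip(fit.grid.event_col, 0, None)]
        own[in_win] = 1.0 / fit.s0[fit.grid.event_col[in_win]]
        G0 = fit.grid.at_risk[:, sel] @ c             # (n,)
        drift = fit.s1[sel].T @ c                     # (p,)
        vA = A.T @ (xiws * e * G0)                    # (q,)
        hA = A @ (Hinv @ vA)                          # (n,)
        if1L = own - if1b @ drift - hA
        if2L = ratio * (-e * G0 + hA) - if2b @ drift
        if2L[xi == 0] = 0.0
    else:
        if1L = np.zeros(n)
        if2L = np.zeros(n)
    out["cumhaz"] = InfluenceSet(
        "cumhaz", _as2d(if2L), _as2d(if1L) + xiw * _as2d(if2L), if1=_as2d(if1L)
    )

    pi, dbeta, dlam_partial = risk_partials(fit, request)
    if1p = if1b @ dbeta.T + if1L[:, None] * dlam_partial[None, :]
    if2p = if2b @ dbeta.T + if2L[:, None] * dlam_partial[None, :]
    out["pure_risk"] = InfluenceSet("pure_risk", if2p, if1p + xiw * if2p, if1=if1p)
    if log_risk:
        if np.any(pi <= 0):
            raise ValidationError("log pure risk undefined: estimated risk is 0")
        out["log_pure_risk"] = InfluenceSet(
            "log_pure_risk",
            if2p / pi[None, :],
            (if1p + xiw * if2p) / pi[None, :],
            if1=if1p / pi[None, :],
        )
    return out


def variance_calibrated(
    infl: InfluenceSet, weights, rule: PairRule, xi, naive: bool = False
) -> VarianceReport:
    """Calibrated total/robust variances and their difference.

    The superpopulation term sums IF1 IF1' + xi w (IF1 IF2' + IF2 IF1')
    + xi w IF2 IF2'; the phase-two pair term involves only the IF2 parts.
    """
    if infl.if1 is None:
        raise ValidationError("calibrated variance requires phase-one influences")
    w = np.asarray(weights, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if1, if2 = infl.if1, infl.if2
    n = if1.shape[0]
    xw = xi * w
    cross = (xw[:, None] * if1).T @ if2
    bracket = if1.T @ if1 + cross + cross.T + (xw[:, None] * if2).T @ if2
    t1 = (n / (n - 1.0)) * bracket
    if naive:
        ph2 = _phase2_naive(xi, w, if2, rule)
    else:
        diag, off = _phase2_blocks(xi, w, if2, rule)
        ph2 = diag + off
    total = t1 + ph2
    delta = infl.delta
    robust = delta.T @ delta
    _, off = _phase2_blocks(xi, w, if2, rule)
    diff = -(1.0 / (n - 1.0)) * bracket - off
    return VarianceReport(
        total=total, robust=robust, phase2_component=ph2, difference=diff,
        method="calibrated",
    )
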