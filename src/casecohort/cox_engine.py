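"""Weighted Cox partial-likelihood estimation, Breslow baseline hazard and pure risk.

The estimating equation is the weighted score

    U(beta) = sum_i s_i * integral { X_i - S1(t)/S0(t) } dN_i(t) = 0,

with risk-set sums ``S_r(t) = sum_k include_k * w_k * Y_k(t) * exp(beta'X_k) X_k^{(r)}``
and per-subject score weights ``s_i`` on the event terms.  Ties are handled by
the Breslow convention: the event-time grid is the set of distinct observed
event times and tied events contribute their summed counts.  The baseline
hazard point mass divides an (optionally reduced) unweighted cohort event
count by S0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AGE, CohortFrame, RiskRequest, ValidationError

__all__ = [
    "CoxFit",
    "SingularInformationError",
    "ConvergenceError",
    "risk_set_sums",
    "solve_weighted_score",
    "cumulative_baseline",
    "pure_risk",
]

BETA_BOUND = 50.0


class SingularInformationError(np.linalg.LinAlgError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class EventGrid:
    """Distinct event times with at-risk and event bookkeeping."""

    times: np.ndarray        # (nt,) sorted distinct event times
    at_risk: np.ndarray      # (n, nt) float 0/1
    dn_total: np.ndarray     # (nt,) unweighted cohort event counts
    event_col: np.ndarray    # (n,) column index of own event, -1 if none


def build_grid(frame: CohortFrame, keep: np.ndarray | None = None) -> EventGrid:
    """Build the event-time grid; ``keep`` optionally masks event times out."""
    is_event = frame.event == 1
    if not is_event.any():
        raise ValidationError("no events in the cohort: Cox fit undefined")
    times = np.unique(frame.exit_time[is_event])
    if keep is not None:
        times = times[keep]
    if frame.timescale == AGE:
        at_risk = (frame.exit_time[:, None] >= times[None, :]) & (
            times[None, :] > frame.entry_time[:, None]
        )
    else:
        at_risk = frame.exit_time[:, None] >= times[None, :]
    event_col = np.full(frame.n, -1, dtype=np.intp)
    idx = np.searchsorted(times, frame.exit_time[is_event])
    ok = (idx < len(times)) & np.isin(frame.exit_time[is_event], times)
    event_col[np.where(is_event)[0][ok]] = idx[ok]
    dn_total = np.bincount(event_col[event_col >= 0], minlength=len(times)).astype(float)
    return EventGrid(
        times=times,
        at_risk=at_risk.astype(float),
        dn_total=dn_total,
        event_col=event_col,
    )


@dataclass
class CoxFit:
    beta: np.ndarray
    event_times: np.ndarray
    jumps: np.ndarray
    s0: np.ndarray
    s1: np.ndarray           # (nt, p)
    s2: np.ndarray           # (nt, p, p)
    info: np.ndarray         # (p, p)
    score_norm: float
    iterations: int
    weights_used: str = "design"
    # internals reused by the influence modules
    grid: EventGrid | None = None
    include: np.ndarray | None = None
    weights: np.ndarray | None = None
    dn_weights: np.ndarray | None = None
    nu: np.ndarray | None = None          # score-weighted event mass per grid time
    numerator: np.ndarray | None = None   # Breslow numerator counts per grid time

    def cumulative_baseline(self, t: float) -> float:
        return float(self.jumps[self.event_times <= t].sum())

    def baseline_increment(self, tau1: float, tau2: float) -> float:
        sel = (self.event_times > tau1) & (self.event_times <= tau2)
        return float(self.jumps[sel].sum())


def _masked_covariates(frame: CohortFrame, include: np.ndarray) -> np.ndarray:
    X = frame.covariates
    if np.isnan(X[include > 0]).any():
        rows = np.where(include > 0)[0]
        bad = rows[np.isnan(X[rows]).any(axis=1)]
        raise ValidationError(
            f"missing covariates for included subjects {list(frame.subject_id[bad][:5])}"
        )
    return np.nan_to_num(X, nan=0.0)


def risk_set_sums(frame, weights, include, beta, t):
    """(S0, S1, S2) at time ``t``: weighted sums over included at-risk subjects."""
    include = np.asarray(include, dtype=float)
    X = _masked_covariates(frame, include)
    y = frame.at_risk(t).astype(float)
    r = include * np.asarray(weights, dtype=float) * y * np.exp(X @ np.asarray(beta, float))
    s0 = r.sum()
    s1 = r @ X
    s2 = (r[:, None] * X).T @ X
    return s0, s1, s2


def _sums_at_grid(X, r, grid: EventGrid):
    """S0, S1, S2 at every grid time for relative-hazard weights ``r``."""
    ry = r[:, None] * grid.at_risk          # (n, nt)
    s0 = ry.sum(axis=0)
    s1 = ry.T @ X                           # (nt, p)
    s2 = np.einsum("ik,ip,iq->kpq", ry, X, X, optimize=True)
    return s0, s1, s2


def _score_and_info(X, s_i, grid, s0, s1, s2):
    """Score vector and information for score weights ``s_i`` on dN terms."""
    nt = len(grid.times)
    nu = np.bincount(
        grid.event_col[grid.event_col >= 0],
        weights=s_i[grid.event_col >= 0],
        minlength=nt,
    )
    M = s1 / s0[:, None]
    has = grid.event_col >= 0
    U = (s_i[has, None] * (X[has] - M[grid.event_col[has]])).sum(axis=0)
    with np.errstate(invalid="ignore"):
        V = s2 / s0[:, None, None] - M[:, :, None] * M[:, None, :]
    info = np.einsum("k,kpq->pq", nu, V)
    return U, info, nu


def solve_weighted_score(
    frame: CohortFrame,
    weights,
    include,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 25,
    dn_weights=None,
    numerator=None,
    grid: EventGrid | None = None,
    weights_used: str = "design",
) -> CoxFit:
    """Newton-Raphson solve of the weighted score with step-halving.

    ``weights`` enter the risk-set sums; ``dn_weights`` (default
    ``include * weights``) weight each subject's event term in the score;
    ``numerator`` (default: unweighted cohort event counts) forms the
    Breslow numerator on the event-time grid.
    """
    include = np.asarray(include, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if grid is None:
        grid = build_grid(frame)
    X = _masked_covariates(frame, include)
    s_i = include * weights if dn_weights is None else np.asarray(dn_weights, float)
    if ((frame.event == 1) & (include * weights > 0) & (s_i <= 0)).any():
        pass  # allowed: e.g. phase-three incomplete cases carry no score weight
    p = X.shape[1]
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()

    def evaluate(b):
        r = include * weights * np.exp(np.clip(X @ b, -700, 700))
        s0, s1, s2 = _sums_at_grid(X, r, grid)
        if (s0 <= 0).any():
            raise ValidationError(
                "empty weighted risk set at an event time; drop undefined times first"
            )
        U, info, nu = _score_and_info(X, s_i, grid, s0, s1, s2)
        return U, info, nu, s0, s1, s2

    U, info, nu, s0, s1, s2 = evaluate(beta)
    norm = np.abs(U).max()
    it = 0
    while norm > tol and it < max_iter:
        it += 1
        try:
            cond = np.linalg.cond(info)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            ev, evec = np.linalg.eigh(info)
            cols = np.where(np.abs(evec[:, 0]) > 1e-3)[0]
            names = [frame.covariate_names[c] for c in cols]
            raise SingularInformationError(
                f"singular information matrix; collinear covariate columns: {names}"
            )
        step = np.linalg.solve(info, U)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            try:
                Uc, infoc, nuc, s0c, s1c, s2c = evaluate(cand)
            except FloatingPointError:
                scale /= 2
                continue
            if np.abs(Uc).max() < norm or scale < 1e-6:
                break
            scale /= 2
        beta, U, info, nu, s0, s1, s2 = cand, Uc, infoc, nuc, s0c, s1c, s2c
        norm = np.abs(U).max()
        if np.abs(beta).max() > BETA_BOUND:
            raise ConvergenceError(
                f"divergent estimate (|beta| > {BETA_BOUND}): monotone likelihood?"
            )
    if norm > tol:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations; last |U|_inf = {norm:.3e}, "
            f"beta = {beta}"
        )
    # degenerate information at the solution: constant/collinear covariates
    # (score identically zero) or monotone likelihood (information -> 0)
    if max_iter > 0:
        eig, evec = np.linalg.eigh(info)
        if eig[0] <= 1e-8 * max(1.0, nu.sum()):
            if np.abs(beta).max() > 10.0:
                raise ConvergenceError(
                    "monotone likelihood: information vanishes at a divergent estimate"
                )
            cols = np.where(np.abs(evec[:, 0]) > 1e-3)[0]
            names = [frame.covariate_names[c] for c in cols]
            raise SingularInformationError(
                f"singular information at the solution; degenerate covariate "
                f"columns: {names}"
            )
    num = grid.dn_total if numerator is None else np.asarray(numerator, dtype=float)
    jumps = num / s0
    return CoxFit(
        beta=beta,
        event_times=grid.times,
        jumps=jumps,
        s0=s0,
        s1=s1,
        s2=s2,
        info=info,
        score_norm=float(norm),
        iterations=it,
        weights_used=weights_used,
        grid=grid,
        include=include,
        weights=weights,
        dn_weights=s_i,
        nu=nu,
        numerator=num,
    )


def cumulative_baseline(fit: CoxFit, t: float) -> float:
    """Breslow cumulative baseline hazard up to ``t`` (right-continuous)."""
    return fit.cumulative_baseline(t)


def pure_risk(fit: CoxFit, request: RiskRequest) -> np.ndarray:
    """Pure covariate-specific risk on (tau1, tau2] per profile."""
    dlam = fit.baseline_increment(request.tau1, request.tau2)
    rel = np.exp(request.profiles @ fit.beta)
    return 1.0 - np.exp(-rel * dlam)
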