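"""Empirical per-subject influences (Taylor deviates) for two-phase estimates.

For design weights the total deviate of subject i is ``Delta_i = xi_i w_i IF2_i``.
The building block shared with the calibrated and three-phase modules is the
score residual

    d_i = int { X_i - S1/S0 } { dN_i(t) - Y_i(t) e^{beta'X_i} nu(t) / S0(t) },

where ``nu(t)`` is the score-weighted event mass on the grid; multiplying by
the inverse information gives the influence on the log-relative hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortFrame, RiskRequest, ValidationError
from .cox_engine import CoxFit, _masked_covariates

__all__ = [
    "InfluenceSet",
    "if2_beta",
    "if2_dlambda",
    "if2_cumhaz",
    "if2_purerisk",
    "influence_design",
    "export_influences",
]


@dataclass
class InfluenceSet:
    """Per-subject influence contributions for one estimand.

    ``delta`` holds the total deviates; ``if1``/``if3`` are present only for
    calibrated / three-phase estimates.  All arrays are (n, d).
    """

    estimand: str
    if2: np.ndarray
    delta: np.ndarray
    if1: np.ndarray | None = None
    if3: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.if2.shape[1]


def _as2d(a: np.ndarray) -> np.ndarray:
    return a if a.ndim == 2 else a[:, None]


def score_residuals(fit: CoxFit, X: np.ndarray) -> np.ndarray:
    """Score residual d_i (n, p) for subjects included in the risk sets.

    The event term uses the subject's own (unweighted) dN; the compensator
    term integrates against the fit's score-weighted event mass ``nu``.
    Rows with include=0 are zero.
    """
    grid = fit.grid
    inc = fit.include
    c = fit.nu / fit.s0                       # (nt,)
    M = fit.s1 / fit.s0[:, None]              # (nt, p)
    e = inc * np.exp(np.clip(X @ fit.beta, -700, 700))
    G0 = grid.at_risk @ c                     # (n,)
    G1 = grid.at_risk @ (c[:, None] * M)      # (n, p)
    d = -e[:, None] * (X * G0[:, None] - G1)
    has = (grid.event_col >= 0) & (inc > 0)
    d[has] += X[has] - M[grid.event_col[has]]
    d[inc == 0] = 0.0
    return d


def if2_beta(frame: CohortFrame, weights, fit: CoxFit) -> np.ndarray:
    """Influence of each subject on the log-relative hazard estimate (n, p)."""
    X = _masked_covariates(frame, fit.include)
    d = score_residuals(fit, X)
    return np.linalg.solve(fit.info, d.T).T


def _event_col_checked(fit: CoxFit, t: float) -> int:
    k = np.searchsorted(fit.event_times, t)
    if k >= len(fit.event_times) or fit.event_times[k] != t:
        raise ValidationError(f"t={t} is not an event time on the fit's grid")
    return int(k)


def if2_dlambda(frame: CohortFrame, weights, fit: CoxFit, t: float, if2b: np.ndarray) -> np.ndarray:
    """Influence on the baseline hazard point mass at event time ``t``."""
    k = _event_col_checked(fit, t)
    X = _masked_covariates(frame, fit.include)
    e = fit.include * np.exp(np.clip(X @ fit.beta, -700, 700))
    dn_i = np.where(fit.grid.event_col == k, 1.0, 0.0) * fit.include
    y = fit.grid.at_risk[:, k]
    out = (dn_i - fit.jumps[k] * y * e) / fit.s0[k]
    out -= (fit.jumps[k] / fit.s0[k]) * (if2b @ fit.s1[k])
    out[fit.include == 0] = 0.0
    return out


def if2_cumhaz(
    frame: CohortFrame, weights, fit: CoxFit, tau1: float, tau2: float, if2b: np.ndarray
) -> np.ndarray:
    """Influence on the cumulative baseline hazard over (tau1, tau2]."""
    sel = (fit.event_times > tau1) & (fit.event_times <= tau2)
    n = frame.n
    if not sel.any():
        return np.zeros(n)
    X = _masked_covariates(frame, fit.include)
    e = fit.include * np.exp(np.clip(X @ fit.beta, -700, 700))
    c = fit.jumps[sel] / fit.s0[sel]
    # own-event term: per-subject dN at own time if inside the window
    own = np.zeros(n)
    has = fit.grid.event_col >= 0
    in_win = has & sel[np.clip(fit.grid.event_col, 0, None)] & (fit.include > 0)
    own[in_win] = 1.0 / fit.s0[fit.grid.event_col[in_win]]
    comp = e * (fit.grid.at_risk[:, sel] @ c)
    drift = fit.s1[sel].T @ c                 # (p,)
    out = own - comp - if2b @ drift
    out[fit.include == 0] = 0.0
    return out


def risk_partials(fit: CoxFit, request: RiskRequest):
    """(pi, d pi/d beta, d pi/d DeltaLambda) per profile, from the pure-risk formula."""
    dlam = fit.baseline_increment(request.tau1, request.tau2)
    rel = np.exp(request.profiles @ fit.beta)      # (k,)
    pi = 1.0 - np.exp(-rel * dlam)
    dbeta = ((1.0 - pi) * rel * dlam)[:, None] * request.profiles   # (k, p)
    dlam_partial = (1.0 - pi) * rel                                 # (k,)
    return pi, dbeta, dlam_partial


def if2_purerisk(
    frame: CohortFrame,
    weights,
    fit: CoxFit,
    request: RiskRequest,
    if2b: np.ndarray,
    if2L: np.ndarray,
    log_scale: bool = False,
) -> np.ndarray:
    """Influence on pure risk (or log pure risk) per profile: (n, k)."""
    pi, dbeta, dlam_partial = risk_partials(fit, request)
    out = if2b @ dbeta.T + if2L[:, None] * dlam_partial[None, :]
    if log_scale:
        if np.any(pi <= 0):
            raise ValidationError("log pure risk undefined: estimated risk is 0")
        out = out / pi[None, :]
    return out


def influence_design(
    frame: CohortFrame,
    weights,
    fit: CoxFit,
    request: RiskRequest | None = None,
    log_risk: bool = True,
) -> dict[str, InfluenceSet]:
    """All design-weight influence sets: beta, and (if requested) the
    cumulative hazard over the risk interval and (log) pure risk per profile."""
    w = np.asarray(weights, dtype=float)
    xiw = (fit.include * w)[:, None]
    out: dict[str, InfluenceSet] = {}
    if2b = if2_beta(frame, w, fit)
    out["beta"] = InfluenceSet("beta", if2b, xiw * if2b)
    if request is not None:
        if2L = if2_cumhaz(frame, w, fit, request.tau1, request.tau2, if2b)
        out["cumhaz"] = InfluenceSet("cumhaz", _as2d(if2L), xiw * _as2d(if2L))
        ifp = if2_purerisk(frame, w, fit, request, if2b, if2L, log_scale=False)
        out["pure_risk"] = InfluenceSet("pure_risk", ifp, xiw * ifp)
        if log_risk:
            ifl = if2_purerisk(frame, w, fit, request, if2b, if2L, log_scale=True)
            out["log_pure_risk"] = InfluenceSet("log_pure_risk", ifl, xiw * ifl)
    return out


def export_influences(frame: CohortFrame, sets: dict[str, InfluenceSet], path) -> None:
    """Write per-subject total deviates to delimited text for audit."""
    rows = []
    for name, s in sets.items():
        for d in range(s.dim):
            col = f"{name}[{d}]" if s.dim > 1 else name
            rows.append(pd.DataFrame({
                "subject_id": frame.subject_id,
                "estimand": col,
                "value": s.delta[:, d],
            }))
    pd.concat(rows).to_csv(path, sep="\t", index=False)
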