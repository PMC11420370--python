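"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's influence/variance code
paths: estimates are recomputed from scratch under per-subject mass
perturbations, risk-set sums use explicit double loops, and the 1-d partial
likelihood is maximized by golden-section search.
"""

from __future__ import annotations

import numpy as np

from casecohort.cox_engine import build_grid, pure_risk, solve_weighted_score


def brute_risk_set_sums(frame, weights, include, beta, t):
    """Explicit O(n) loop version of (S0, S1, S2)."""
    p = frame.covariates.shape[1]
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    for i in range(frame.n):
        if include[i] == 0:
            continue
        if frame.timescale == "age":
            y = frame.exit_time[i] >= t > frame.entry_time[i]
        else:
            y = frame.exit_time[i] >= t
        if not y:
            continue
        x = frame.covariates[i]
        r = weights[i] * np.exp(float(x @ beta))
        s0 += r
        s1 += r * x
        s2 += r * np.outer(x, x)
    return s0, s1, s2


def log_partial_likelihood_1d(frame, weights, include, beta):
    """Weighted Breslow log partial likelihood for p=1 (scalar beta)."""
    x = frame.covariates[:, 0]
    ll = 0.0
    for i in range(frame.n):
        if frame.event[i] != 1:
            continue
        t = frame.exit_time[i]
        s0 = 0.0
        for k in range(frame.n):
            if include[k] == 0 or frame.exit_time[k] < t:
                continue
            if frame.timescale == "age" and not (t > frame.entry_time[k]):
                continue
            s0 += weights[k] * np.exp(beta * x[k])
        w_i = include[i] * weights[i]
        ll += w_i * (beta * x[i] - np.log(s0))
    return ll


def log_partial_likelihood(frame, weights, include, beta):
    """Weighted Breslow log partial likelihood, explicit loops, any p."""
    beta = np.asarray(beta, dtype=float)
    X = frame.covariates
    ll = 0.0
    for i in range(frame.n):
        if frame.event[i] != 1:
            continue
        t = frame.exit_time[i]
        s0 = 0.0
        for k in range(frame.n):
            if include[k] == 0 or frame.exit_time[k] < t:
                continue
            if frame.timescale == "age" and not (t > frame.entry_time[k]):
                continue
            s0 += weights[k] * np.exp(float(X[k] @ beta))
        ll += include[i] * weights[i] * (float(X[i] @ beta) - np.log(s0))
    return ll


def golden_section_max(f, lo, hi, tol=1e-10):
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
    return (a + b) / 2


def design_estimates(frame, weights, xi, request, mass):
    """Design-weight estimates under per-subject mass perturbation."""
    grid = build_grid(frame)
    has = grid.event_col >= 0
    num = np.bincount(grid.event_col[has], weights=mass[has], minlength=len(grid.times))
    fit = solve_weighted_score(
        frame, mass * weights, xi,
        dn_weights=mass * xi * weights, numerator=num, grid=grid, tol=1e-12,
    )
    lam = fit.baseline_increment(request.tau1, request.tau2)
    pis = pure_risk(fit, request)
    return fit.beta, lam, pis


def calibrated_estimates(frame, weights, A, xi, request, mass, eta0=None):
    """Calibrated estimates with the raking equation re-solved under mass."""
    target = (mass[:, None] * A).sum(axis=0)
    eta = np.zeros(A.shape[1]) if eta0 is None else eta0.copy()
    for _ in range(100):
        ws = mass * xi * weights * np.exp(A @ eta)
        g = ws @ A - target
        if np.abs(g).max() < 1e-13 * max(1.0, np.abs(target).max()):
            break
        H = (ws[:, None] * A).T @ A
        eta = eta - np.linalg.solve(H, g)
    wstar = weights * np.exp(A @ eta)
    grid = build_grid(frame)
    has = grid.event_col >= 0
    num = np.bincount(grid.event_col[has], weights=mass[has], minlength=len(grid.times))
    fit = solve_weighted_score(
        frame, mass * wstar, xi,
        dn_weights=mass * xi * wstar, numerator=num, grid=grid, tol=1e-12,
    )
    lam = fit.baseline_increment(request.tau1, request.tau2)
    pis = pure_risk(fit, request)
    return fit.beta, lam, pis


def threephase_estimates(frame, w2, strata3_codes, n_strata3, request, mass):
    """Three-phase estimates with per-stratum ratio weights re-solved under mass."""
    xi = (frame.xi == 1).astype(float)
    v = (frame.v == 1).astype(float)
    n2 = np.bincount(strata3_codes, weights=mass * xi, minlength=n_strata3)
    n3 = np.bincount(strata3_codes, weights=mass * xi * v, minlength=n_strata3)
    w3 = (n2 / n3)[strata3_codes]
    inc = xi * v
    wt = w2 * w3
    grid = build_grid(frame)
    keep = (grid.at_risk * inc[:, None]).sum(axis=0) > 0
    grid2 = build_grid(frame, keep=keep)
    has = grid2.event_col >= 0
    num = np.bincount(grid2.event_col[has], weights=mass[has], minlength=len(grid2.times))
    fit = solve_weighted_score(
        frame, mass * wt, inc,
        dn_weights=mass * inc * wt, numerator=num, grid=grid2, tol=1e-12,
    )
    lam = fit.baseline_increment(request.tau1, request.tau2)
    pis = pure_risk(fit, request)
    return fit.beta, lam, pis


def central_difference(estimates_fn, n, i, eps=1e-5):
    """w_i * d(estimate)/d(mass_i) by central differences."""
    mass = np.ones(n)
    mass[i] = 1 + eps
    up = estimates_fn(mass)
    mass[i] = 1 - eps
    dn = estimates_fn(mass)
    return [(a - b) / (2 * eps) for a, b in zip(up, dn)]
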