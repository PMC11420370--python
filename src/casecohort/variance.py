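"""Joint sampling weights/covariances and two-phase variance estimation.

The total variance estimate combines a superpopulation (phase-one) term with
a finite-population (phase-two) double sum over within-stratum pairs whose
joint inclusion weights and covariances depend on the sampling mode.  The
"robust" estimator is the plain sum of squared total deviates; its excess
over the two-phase estimate is returned as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import CohortFrame, DesignWeights, ValidationError
from .influence import InfluenceSet

__all__ = [
    "PairRule",
    "VarianceReport",
    "pair_rule",
    "variance_twophase",
    "variance_robust",
    "variance_difference",
    "confidence_interval",
]


@dataclass
class PairRule:
    """Per-stratum joint-weight and covariance scalars for sampling pairs.

    ``w_pair``/``sigma_pair`` apply to ordered pairs of distinct non-cases in
    a stratum, ``sigma_diag`` to a single non-case; any pair involving a case
    has covariance 0 and joint weight equal to the product of the marginal
    weights.
    """

    mode: str
    w_pair: np.ndarray        # (J,)
    sigma_pair: np.ndarray    # (J,)
    sigma_diag_noncase: np.ndarray  # (J,) for without_replacement; per-subject for bernoulli
    stratum: np.ndarray       # (n,) codes
    noncase: np.ndarray       # (n,) bool
    w_marginal: np.ndarray    # (n,)
    sigma_diag: np.ndarray    # (n,) per-subject diagonal covariance

    def joint_weight(self, i: int, k: int) -> float:
        if i == k:
            return self.w_marginal[i]
        if (
            self.noncase[i]
            and self.noncase[k]
            and self.stratum[i] == self.stratum[k]
            and self.mode == "without_replacement"
        ):
            return float(self.w_pair[self.stratum[i]])
        return float(self.w_marginal[i] * self.w_marginal[k])

    def sigma(self, i: int, k: int) -> float:
        if self.stratum[i] != self.stratum[k]:
            return 0.0
        if i == k:
            return float(self.sigma_diag[i])
        if self.noncase[i] and self.noncase[k] and self.mode == "without_replacement":
            return float(self.sigma_pair[self.stratum[i]])
        return 0.0


@dataclass
class VarianceReport:
    total: np.ndarray
    robust: np.ndarray
    phase2_component: np.ndarray
    difference: np.ndarray
    method: str

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.total))

    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust))


def pair_rule(frame: CohortFrame, weights: DesignWeights, mode: str | None = None) -> PairRule:
    """Joint weights/covariances for the frame's sampling design."""
    mode = mode or weights.mode
    noncase = frame.event == 0
    sizes = frame.stratum_sizes().astype(float)
    J = frame.n_strata
    w_marginal = weights.w2
    sigma_diag = np.zeros(frame.n)
    if mode == "without_replacement":
        m = weights.m.astype(float)
        if (m <= 1).any():
            raise ValidationError("m(j) <= 1: pairwise weights undefined")
        n_j = sizes
        w_pair = n_j * (n_j - 1) / (m * (m - 1))
        f = m / n_j
        sigma_pair = f * (m - 1) / (n_j - 1) - f**2
        sigma_diag_nc = f * (1 - f)
        sigma_diag[noncase] = sigma_diag_nc[frame.stratum[noncase]]
    elif mode == "bernoulli":
        w_pair = np.zeros(J)
        sigma_pair = np.zeros(J)
        sigma_diag_nc = np.zeros(J)
        pi = 1.0 / w_marginal
        sigma_diag[noncase] = (pi * (1 - pi))[noncase]
    else:
        raise ValidationError(f"unknown sampling mode {mode!r}")
    return PairRule(
        mode=mode,
        w_pair=w_pair,
        sigma_pair=sigma_pair,
        sigma_diag_noncase=sigma_diag_nc,
        stratum=frame.stratum,
        noncase=noncase,
        w_marginal=w_marginal,
        sigma_diag=sigma_diag,
    )


def _phase2_blocks(xi, w, if2, rule: PairRule):
    """(diagonal term, off-diagonal pair term) of the sigma-weighted double sum.

    Grouped per stratum: within a stratum all sampled non-cases share the
    same marginal weight, pair weight and covariances, so the double sum
    reduces to rank-one updates on group sums.
    """
    d = if2.shape[1]
    a = (xi * w)[:, None] * if2            # xi w IF2
    diag = np.einsum("i,ij,ik->jk", rule.w_marginal * rule.sigma_diag * xi, if2 * w[:, None], if2 * w[:, None])
    off = np.zeros((d, d))
    if rule.mode == "without_replacement":
        for j in range(len(rule.w_pair)):
            sel = (rule.stratum == j) & rule.noncase & (xi > 0)
            if not sel.any():
                continue
            S = a[sel].sum(axis=0)
            Q = a[sel].T @ a[sel]
            off += rule.w_pair[j] * rule.sigma_pair[j] * (np.outer(S, S) - Q)
    return diag, off


def _phase2_naive(xi, w, if2, rule: PairRule):
    """O(n^2) reference double sum (used by the self-check battery/tests)."""
    n, d = if2.shape
    out = np.zeros((d, d))
    idx = np.where(xi > 0)[0]
    for i in idx:
        for k in idx:
            s = rule.sigma(i, k)
            if s == 0.0:
                continue
            out += (
                rule.joint_weight(i, k)
                * s
                * w[i]
                * w[k]
                * np.outer(if2[i], if2[k])
            )
    return out


def variance_twophase(
    infl: InfluenceSet, weights, rule: PairRule, xi=None, naive: bool = False
) -> VarianceReport:
    """Two-phase variance, robust variance and their difference for one estimand."""
    w = np.asarray(weights, dtype=float)
    if2 = infl.if2
    n = if2.shape[0]
    if xi is None:
        xi = (np.abs(infl.delta).sum(axis=1) > 0).astype(float) if infl.delta is not None else np.ones(n)
    xi = np.asarray(xi, dtype=float)
    if w.shape[0] != n:
        raise ValidationError("weights/influence shape mismatch")
    a = (xi * w)[:, None] * if2
    t1 = (n / (n - 1.0)) * np.einsum("i,ij,ik->jk", xi * w, if2, if2)
    if naive:
        ph2 = _phase2_naive(xi, w, if2, rule)
    else:
        diag, off = _phase2_blocks(xi, w, if2, rule)
        ph2 = diag + off
    total = t1 + ph2
    robust = a.T @ a
    diff = robust - total
    return VarianceReport(
        total=total, robust=robust, phase2_component=ph2, difference=diff,
        method="twophase",
    )


def variance_robust(infl: InfluenceSet) -> VarianceReport:
    """Sum of squared total deviates over all subjects."""
    d = infl.delta
    robust = d.T @ d
    return VarianceReport(
        total=robust, robust=robust,
        phase2_component=np.zeros_like(robust),
        difference=np.zeros_like(robust),
        method="robust",
    )


def variance_difference(infl: InfluenceSet, weights, rule: PairRule, xi=None) -> np.ndarray:
    """Robust minus two-phase estimate, computed directly from its own formula:
    -(1/(n-1)) * sum xi w IF2 IF2' minus the off-diagonal pair double sum."""
    w = np.asarray(weights, dtype=float)
    if2 = infl.if2
    n = if2.shape[0]
    if xi is None:
        xi = (np.abs(infl.delta).sum(axis=1) > 0).astype(float)
    xi = np.asarray(xi, dtype=float)
    t = (1.0 / (n - 1.0)) * np.einsum("i,ij,ik->jk", xi * w, if2, if2)
    _, off = _phase2_blocks(xi, w, if2, rule)
    return -t - off


def confidence_interval(estimate, variance, level: float = 0.95, transform: str = "identity"):
    """Normal-theory interval; ``transform='log'`` builds it on the log scale
    (``variance`` is then the variance of the log estimate) and exponentiates."""
    estimate = np.asarray(estimate, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < 0):
        raise ValidationError("negative variance")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(variance)
    if transform == "identity":
        return estimate - z * se, estimate + z * se
    if transform == "log":
        if np.any(estimate <= 0):
            raise ValidationError("log-scale interval requires a positive estimate")
        return estimate * np.exp(-z * se), estimate * np.exp(z * se)
    raise ValidationError(f"unknown transform {transform!r}")
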