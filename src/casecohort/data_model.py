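"""Domain types, validation and delimited-text I/O for case-cohort data.

A cohort is stored column-wise in a :class:`CohortFrame`.  Subjects carry a
sampling stratum, follow-up interval, event indicator, phase-two (``xi``)
and phase-three (``v``) sampling indicators, a covariate matrix whose
phase-two columns may be missing outside the phase-two sample, and a matrix
of phase-one proxy variables observed for everybody.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortFrame",
    "DesignWeights",
    "RiskRequest",
    "ConfigError",
    "DesignViolationError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "design_weights",
]

TIME_ON_STUDY = "time_on_study"
AGE = "age"


class ConfigError(ValueError):
    """Raised when a column map or config file is incomplete or inconsistent."""


class DesignViolationError(ValueError):
    """Raised when the data contradict the sampling design (e.g. a case with xi=0)."""


class ValidationError(ValueError):
    """Raised when subject-level values are invalid (e.g. non-positive follow-up)."""


@dataclass
class CohortFrame:
    """Per-subject phase-one data, sampling indicators and covariates.

    Covariate entries may be NaN only for subjects outside the phase-two
    sample (or outside phase three when ``v`` is informative); this is
    checked by :meth:`validate`.
    """

    subject_id: np.ndarray
    stratum: np.ndarray          # int codes 0..J-1
    stratum_labels: np.ndarray   # original label per stratum code
    entry_time: np.ndarray
    exit_time: np.ndarray
    event: np.ndarray
    xi: np.ndarray
    v: np.ndarray
    covariates: np.ndarray       # (n, p), NaN = missing
    covariate_names: list[str]
    proxies: np.ndarray          # (n, q0), fully observed
    proxy_names: list[str] = field(default_factory=list)
    timescale: str = TIME_ON_STUDY

    @property
    def n(self) -> int:
        return len(self.exit_time)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_strata(self) -> int:
        return len(self.stratum_labels)

    def stratum_sizes(self) -> np.ndarray:
        return np.bincount(self.stratum, minlength=self.n_strata)

    def at_risk(self, t: float) -> np.ndarray:
        """At-risk indicator at time/age ``t`` on the frame's timescale."""
        if self.timescale == AGE:
            return (self.exit_time >= t) & (t > self.entry_time)
        return self.exit_time >= t

    def validate(self) -> None:
        ev = np.asarray(self.event)
        if not np.isin(ev, [0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        bad = self.exit_time <= self.entry_time
        if bad.any():
            who = self.subject_id[bad][:5]
            raise ValidationError(
                f"non-positive follow-up (exit_time <= entry_time) for subjects {list(who)}"
            )
        viol = (ev == 1) & (self.xi == 0)
        if viol.any():
            who = self.subject_id[viol][:5]
            raise DesignViolationError(
                f"case(s) with xi=0 violate the all-cases design: subjects {list(who)}"
            )
        in3 = (self.xi == 1) & (self.v == 1)
        if np.isnan(self.covariates[in3]).any():
            rows = np.where(in3)[0][np.isnan(self.covariates[in3]).any(axis=1)]
            who = self.subject_id[rows][:5]
            raise ValidationError(
                f"missing covariates for phase-two/three subjects {list(who)}"
            )
        if (self.v == 0).any() and ((self.v == 1) & (self.xi == 0)).any():
            # v is informative (has zeros) yet claims complete data outside phase two
            raise ValidationError("v=1 outside the phase-two sample")
        if self.proxies.size and np.isnan(self.proxies).any():
            raise ValidationError("proxy variables must be observed for all subjects")

    def copy(self) -> "CohortFrame":
        return replace(
            self,
            subject_id=self.subject_id.copy(),
            stratum=self.stratum.copy(),
            stratum_labels=self.stratum_labels.copy(),
            entry_time=self.entry_time.copy(),
            exit_time=self.exit_time.copy(),
            event=self.event.copy(),
            xi=self.xi.copy(),
            v=self.v.copy(),
            covariates=self.covariates.copy(),
            covariate_names=list(self.covariate_names),
            proxies=self.proxies.copy(),
            proxy_names=list(self.proxy_names),
        )


@dataclass
class DesignWeights:
    """Marginal design weights and the sampling mode they derive from."""

    w2: np.ndarray
    w3: np.ndarray
    mode: str                    # "without_replacement" | "bernoulli"
    m: np.ndarray                # subcohort draws per stratum
    calibrated: np.ndarray | None = None

    @property
    def combined(self) -> np.ndarray:
        return self.w2 * self.w3

    def effective(self) -> np.ndarray:
        """Weights to use for estimation: calibrated if present, else design."""
        return self.calibrated if self.calibrated is not None else self.combined


@dataclass
class RiskRequest:
    """Half-open risk-projection interval (tau1, tau2] and covariate profiles."""

    tau1: float
    tau2: float
    profiles: np.ndarray         # (k, p)

    def __post_init__(self):
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if not self.tau2 > self.tau1:
            raise ValidationError(
                f"empty risk interval: tau1={self.tau1} >= tau2={self.tau2}"
            )


def _codes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary stratum labels to contiguous codes in sorted label order."""
    uniq = np.unique(labels)
    codes = np.searchsorted(uniq, labels)
    return codes.astype(np.intp), uniq


def build_frame(
    *,
    subject_id,
    stratum,
    entry_time,
    exit_time,
    event,
    xi,
    v=None,
    covariates,
    covariate_names=None,
    proxies=None,
    proxy_names=None,
    timescale=TIME_ON_STUDY,
    validate=True,
) -> CohortFrame:
    """Assemble and validate a :class:`CohortFrame` from arrays."""
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    n = covariates.shape[0]
    if v is None:
        v = np.ones(n, dtype=np.int8)
    if proxies is None:
        proxies = np.empty((n, 0))
    codes, labels = _codes(np.asarray(stratum))
    frame = CohortFrame(
        subject_id=np.asarray(subject_id),
        stratum=codes,
        stratum_labels=labels,
        entry_time=np.asarray(entry_time, dtype=float),
        exit_time=np.asarray(exit_time, dtype=float),
        event=np.asarray(event, dtype=np.int8),
        xi=np.asarray(xi, dtype=np.int8),
        v=np.asarray(v, dtype=np.int8),
        covariates=covariates,
        covariate_names=list(covariate_names)
        if covariate_names is not None
        else [f"x{i + 1}" for i in range(covariates.shape[1])],
        proxies=np.asarray(proxies, dtype=float),
        proxy_names=list(proxy_names) if proxy_names is not None else [],
        timescale=timescale,
    )
    if validate:
        frame.validate()
    return frame


_REQUIRED_KEYS = ("subject_id", "stratum", "exit_time", "event", "xi")


def read_cohort(path, config: dict) -> CohortFrame:
    """Read a delimited text file into a validated :class:`CohortFrame`.

    ``config`` maps roles to column names: required keys ``subject_id``,
    ``stratum``, ``exit_time``, ``event``, ``xi``, ``covariates`` (list);
    optional ``entry_time``, ``v``, ``proxies`` (list) and ``timescale``.
    The delimiter is inferred from the extension (``.csv`` -> comma,
    otherwise tab).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")
        if config[key] not in df.columns:
            raise ConfigError(f"column {config[key]!r} (for {key!r}) not in file")
    cov_cols = config.get("covariates")
    if not cov_cols:
        raise ConfigError("config missing required key 'covariates'")
    for c in cov_cols:
        if c not in df.columns:
            raise ConfigError(f"covariate column {c!r} not in file")
    proxy_cols = config.get("proxies", [])
    for c in proxy_cols:
        if c not in df.columns:
            raise ConfigError(f"proxy column {c!r} not in file")
    n = len(df)
    entry = (
        df[config["entry_time"]].to_numpy(dtype=float)
        if "entry_time" in config
        else np.zeros(n)
    )
    v = df[config["v"]].to_numpy() if "v" in config else None
    return build_frame(
        subject_id=df[config["subject_id"]].to_numpy(),
        stratum=df[config["stratum"]].to_numpy(),
        entry_time=entry,
        exit_time=df[config["exit_time"]].to_numpy(dtype=float),
        event=df[config["event"]].to_numpy(),
        xi=df[config["xi"]].to_numpy(),
        v=v,
        covariates=df[cov_cols].to_numpy(dtype=float),
        covariate_names=cov_cols,
        proxies=df[proxy_cols].to_numpy(dtype=float) if proxy_cols else None,
        proxy_names=proxy_cols,
        timescale=config.get("timescale", TIME_ON_STUDY),
    )


def write_cohort(frame: CohortFrame, path, config: dict | None = None) -> dict:
    """Write a frame back to delimited text (missing values as empty fields).

    Returns the column map needed to read the file back.
    """
    config = config or {}
    cols = {
        config.get("subject_id", "subject_id"): frame.subject_id,
        config.get("stratum", "stratum"): frame.stratum_labels[frame.stratum],
        config.get("entry_time", "entry_time"): frame.entry_time,
        config.get("exit_time", "exit_time"): frame.exit_time,
        config.get("event", "event"): frame.event,
        config.get("xi", "xi"): frame.xi,
        config.get("v", "v"): frame.v,
    }
    for j, name in enumerate(frame.covariate_names):
        cols[name] = frame.covariates[:, j]
    for j, name in enumerate(frame.proxy_names):
        cols[name] = frame.proxies[:, j]
    df = pd.DataFrame(cols)
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)
    return {
        "subject_id": config.get("subject_id", "subject_id"),
        "stratum": config.get("stratum", "stratum"),
        "entry_time": config.get("entry_time", "entry_time"),
        "exit_time": config.get("exit_time", "exit_time"),
        "event": config.get("event", "event"),
        "xi": config.get("xi", "xi"),
        "v": config.get("v", "v"),
        "covariates": list(frame.covariate_names),
        "proxies": list(frame.proxy_names),
        "timescale": frame.timescale,
    }


def design_weights(frame: CohortFrame, m, mode: str = "without_replacement") -> DesignWeights:
    """Phase-two design weights: n(j)/m(j) for non-cases, 1 for cases.

    ``m`` gives the subcohort size per stratum (in sorted-label order, or a
    mapping from stratum label to size).
    """
    sizes = frame.stratum_sizes()
    if isinstance(m, dict):
        by_str = {str(k): v for k, v in m.items()}
        try:
            m_arr = np.array([by_str[str(lab)] for lab in frame.stratum_labels], dtype=int)
        except KeyError as exc:
            raise ConfigError(f"no subcohort size m for stratum {exc}") from exc
    else:
        m_arr = np.asarray(m, dtype=int)
    if m_arr.shape != (frame.n_strata,):
        raise ConfigError(
            f"m has {m_arr.size} entries but the frame has {frame.n_strata} strata"
        )
    if (m_arr > sizes).any():
        raise ValidationError("m(j) exceeds stratum size n(j)")
    if mode == "without_replacement" and (m_arr <= 1).any():
        raise ValidationError(
            "m(j) <= 1 with without-replacement sampling: the joint weight "
            "n(n-1)/(m(m-1)) is undefined"
        )
    if mode not in ("without_replacement", "bernoulli"):
        raise ConfigError(f"unknown sampling mode {mode!r}")
    w2 = np.ones(frame.n)
    noncase = frame.event == 0
    w2[noncase] = (sizes / m_arr)[frame.stratum[noncase]]
    return DesignWeights(
        w2=w2, w3=np.ones(frame.n), mode=mode, m=m_arr, calibrated=None
    )
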