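"""Survival machinery for median-split risk groups.

Kaplan–Meier product-limit estimation with Greenwood confidence
intervals on the log(−log S) scale (the "log-log" interval type), the
unweighted two-group Mantel–Haenszel log-rank test, and a Cox
proportional-hazards fit for a single binary status covariate.

KM and the log-rank test are delegated to lifelines.  The Cox fit is a
direct Newton maximization of the partial likelihood with Breslow tie
handling: for a scalar binary covariate the score and information have
closed forms over the distinct event times, so the fit is exact, fast,
and its conventions (Breslow ties; censored subjects at an event time
remain in that time's risk set) are stated rather than inherited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .scoring import ScoreVector, assign_risk, assign_status, score_mean, score_reflected_median
from .signatures import GeneSignature

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "stratified_km_report",
]


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    conf_level: float = 0.95


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    log_hr: float
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    converged: bool
    n_events: int


def _validate_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if not np.all(np.isfinite(t)) or (t < 0).any():
        raise ValueError("times must be finite and nonnegative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be coded 0 (censored) / 1 (event)")
    return t, e.astype(int)


def km_estimate(times, events, conf_level: float = 0.95) -> KMCurve:
    """Product-limit survival estimate with log-log Greenwood CIs.

    Returns the curve evaluated at the distinct observed event times; a
    cohort with no events yields S == 1 and empty arrays.
    """
    t, e = _validate_surv(times, events)
    if e.sum() == 0:
        empty = np.array([])
        return KMCurve(empty, empty, empty.astype(int), empty, empty, conf_level)
    kmf = KaplanMeierFitter(alpha=1.0 - conf_level)
    kmf.fit(t, e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    ts = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ts].iloc[:, 0].to_numpy()
    ci = kmf.confidence_interval_.loc[ts]
    return KMCurve(
        event_times=ts,
        survival=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        conf_level=conf_level,
    )


def logrank_test(times, events, group) -> LogRankResult:
    """Unweighted Mantel–Haenszel log-rank test between two groups.

    ``group`` is a binary label per subject.  Both groups must be
    non-empty and at least one event must be observed.
    """
    t, e = _validate_surv(times, events)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group labels must match times in length")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("logrank_test requires exactly two non-empty groups")
    if e.sum() == 0:
        raise ValueError("logrank_test requires at least one event")
    a = g == levels[0]
    res = _ll_logrank(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return LogRankResult(
        chi_square=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )


def _cox_score_info(beta: float, groups: list[tuple[int, int, int, int]]):
    """Score and information of the Breslow partial likelihood.

    ``groups`` holds, per distinct event time, (d_j, s_j, n0_j, n1_j):
    events, events with covariate 1, and risk-set counts per covariate
    level.  For a binary covariate the risk-set mean of the covariate is
    p_j = n1 e^b / (n0 + n1 e^b); score = sum s_j - d_j p_j, information
    = sum d_j p_j (1 - p_j).
    """
    eb = np.exp(beta)
    score = 0.0
    info = 0.0
    loglik = 0.0
    for d, s, n0, n1 in groups:
        denom = n0 + n1 * eb
        p = n1 * eb / denom
        score += s - d * p
        info += d * p * (1.0 - p)
        loglik += beta * s - d * np.log(denom)
    return loglik, score, info


def _event_time_groups(t, e, x):
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    groups = []
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj  # censored exactly at tj stay in the risk set
        ev = (t == tj) & (e == 1)
        d = int(ev.sum())
        s = int(x[ev].sum())
        n1 = int(x[at_risk].sum())
        n0 = int(at_risk.sum()) - n1
        groups.append((d, s, n0, n1))
    return groups


def cox_fit(times, events, status, conf_level: float = 0.95) -> CoxResult:
    """Cox proportional-hazards fit of a single binary covariate.

    Newton–Raphson maximization of the Breslow partial likelihood,
    iterated to |score| < 1e-8 or 50 iterations.  Monotone likelihoods
    (e.g. all events in one group) are reported through
    ``converged=False`` with the last bounded estimate rather than a
    spurious finite HR.
    """
    t, e = _validate_surv(times, events)
    x = np.asarray(status)
    if x.shape != t.shape:
        raise ValueError("status must match times in length")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("status must be binary 0/1")
    x = x.astype(int)
    if x.min() == x.max():
        raise ValueError("no variation in status covariate")
    if e.sum() == 0:
        raise ValueError("cox_fit requires at least one event")
    if e[x == 0].sum() == 0 or e[x == 1].sum() == 0:
        warnings.warn(
            "no events in one status level: partial likelihood may be monotone",
            UserWarning,
            stacklevel=2,
        )
    groups = _event_time_groups(t, e, x)

    beta = 0.0
    converged = False
    for _ in range(50):
        _, score, info = _cox_score_info(beta, groups)
        if abs(score) < 1e-8:
            converged = True
            break
        if info <= 0:
            break
        beta += score / info
        if abs(beta) > 20:  # monotone likelihood guard
            break
    _, score, info = _cox_score_info(beta, groups)
    converged = converged or abs(score) < 1e-8
    if abs(beta) > 20:
        converged = False
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if np.isfinite(se) else 1.0
    with np.errstate(over="ignore"):  # monotone fits: CI bound may overflow to inf
        hr, lo, hi = np.exp(beta), np.exp(beta - z * se), np.exp(beta + z * se)
    return CoxResult(
        log_hr=float(beta),
        hr=float(hr),
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=float(p),
        converged=bool(converged),
        n_events=int(e.sum()),
    )


def stratified_km_report(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    signature: GeneSignature,
    method: str = "reflected_median",
    conf_level: float = 0.95,
) -> dict:
    """Score a cohort, median-split it, and quantify survival separation.

    Composes scoring -> median-split risk assignment -> per-group KM +
    log-rank + Cox(status).  The Cox covariate is the polarity-aware
    risk group (1 = higher-risk), so HR > 1 means the signature-positive
    group does worse.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    common = [s for s in expr.columns if s in clin.index]
    if not common:
        raise ValueError("no overlapping sample ids between expression and clinical")
    sub = expr[common]
    if method == "reflected_median":
        scores = score_reflected_median(sub, signature)
    elif method == "mean":
        scores = score_mean(sub, signature.genes, name=signature.name)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    risk = assign_risk(scores)
    status = assign_status(scores)
    t = clin.loc[common, "time"].to_numpy(dtype=float)
    e = clin.loc[common, "event"].to_numpy(dtype=int)
    r = risk.loc[common].to_numpy()
    km_high = km_estimate(t[r == 1], e[r == 1], conf_level)
    km_low = km_estimate(t[r == 0], e[r == 0], conf_level)
    lr = logrank_test(t, e, r)
    cox = cox_fit(t, e, r, conf_level)
    return {
        "signature": signature.name,
        "method": method,
        "threshold": status.threshold,
        "n_risk_high": int((r == 1).sum()),
        "n_risk_low": int((r == 0).sum()),
        "km_risk_high": km_high,
        "km_risk_low": km_low,
        "logrank": lr,
        "cox": cox,
        "scores": scores,
        "risk": risk,
    }
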