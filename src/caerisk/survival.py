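"""Kaplan-Meier estimation, log-rank tests and time-window-stratified odds ratios.

The product-limit estimator and the k-group log-rank test are implemented
directly (events processed before censorings at tied times, the standard
convention).  ``stratified_window_or`` assigns matched sets to disjoint
follow-up windows by the case's event time and fits the conditional
logistic model within each window, reproducing the short-term /
long-term stratification of matched surveillance analyses.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clogit import CLogitFit, Term, fit_matched
from .exceptions import ConfigError, ConvergenceError, DataError

INF = float("inf")

#: Default follow-up windows (years, half-open (lo, hi]): within the first
#: year of adenoma removal, the second, the third, and beyond three years.
DEFAULT_WINDOWS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, INF))


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    ``times`` are non-negative follow-up times; ``events`` flag whether the
    subject's time is an event (True) or a censoring (False).  At tied
    times, events are handled before censorings reduce the risk set.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise DataError("no observations")
    if len(t) != len(e):
        raise DataError("times and events differ in length")
    if (t < 0).any():
        raise DataError("negative times")

    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = len(t)
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))  # still at risk just before et
        d_i = int(np.sum((t == et) & e))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        n_ev.append(d_i)
        surv.append(s)
    return KMEstimate(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        n_events=np.array(n_ev),
    )


def logrank_test(group_labels, times, events) -> tuple[float, float, int]:
    """k-group log-rank test; returns (chi2, p, df) with df = k−1.

    Observed-minus-expected event counts are accumulated over the pooled
    distinct event times with the hypergeometric variance (and covariance
    for k > 2); the statistic uses the first k−1 groups.
    """
    g = np.asarray(group_labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (len(g) == len(t) == len(e)):
        raise DataError("group_labels, times and events must have equal length")
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise DataError("need at least two groups")
    for lab in labels:
        if not np.any(g == lab):
            raise DataError(f"group {lab!r} has no observations")

    event_times = np.unique(t[e])
    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n_j = float(at_risk.sum())
        d_j = float(((t == et) & e).sum())
        if n_j <= 1 or d_j == 0:
            continue
        n_gj = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        d_gj = np.array([((t == et) & e & (g == lab)).sum() for lab in labels], dtype=float)
        exp_gj = d_j * n_gj / n_j
        OmE += d_gj - exp_gj
        frac = n_gj / n_j
        scale = d_j * (n_j - d_j) / (n_j - 1.0)
        V += scale * (np.diag(frac) - np.outer(frac, frac))
    df = k - 1
    Vr = V[:df, :df]
    try:
        chi2 = float(OmE[:df] @ np.linalg.solve(Vr, OmE[:df]))
    except np.linalg.LinAlgError:
        chi2 = float(OmE[:df] @ np.linalg.pinv(Vr) @ OmE[:df])
    return chi2, float(stats.chi2.sf(chi2, df=df)), df


def _check_windows(windows) -> list[tuple[float, float]]:
    ws = sorted((float(a), float(b)) for a, b in windows)
    for (a, b) in ws:
        if not b > a:
            raise ConfigError(f"window ({a}, {b}] is empty")
    for (a1, b1), (a2, b2) in zip(ws, ws[1:]):
        if a2 < b1:
            raise ConfigError(f"windows ({a1}, {b1}] and ({a2}, {b2}] overlap")
    return ws


def window_label(window: tuple[float, float]) -> str:
    a, b = window
    return f">{a:g} years" if math.isinf(b) else f">{a:g}-<={b:g} years"


def stratified_window_or(
    sets_df: pd.DataFrame,
    covariates: pd.DataFrame,
    terms: list[Term],
    windows=DEFAULT_WINDOWS,
    **fit_kwargs,
) -> dict[tuple[float, float], CLogitFit | None]:
    """Per-window conditional-logistic fits stratified by case event time.

    Each matched set falls in the window whose half-open interval
    (lo, hi] contains its index time.  Windows containing no informative
    set, or in which the odds ratio is not estimable (separation in a
    sparse stratum), map to ``None`` (flagged, not fitted).
    """
    ws = _check_windows(windows)
    out: dict[tuple[float, float], CLogitFit | None] = {}
    for (lo, hi) in ws:
        mask = (sets_df["index_time_years"] > lo) & (sets_df["index_time_years"] <= hi)
        sub = sets_df[mask]
        if sub.empty:
            out[(lo, hi)] = None
            continue
        try:
            out[(lo, hi)] = fit_matched(sub, covariates, terms, **fit_kwargs)
        except (DataError, ConvergenceError):
            out[(lo, hi)] = None
    return out


def km_by_group(
    df: pd.DataFrame,
    group_col: str,
    time_col: str = "event_time_years",
    event_col: str = "event",
    max_years: float | None = None,
) -> dict[object, KMEstimate]:
    """Kaplan-Meier curves per level of a baseline classification.

    ``max_years`` administratively truncates follow-up (observations
    beyond it are censored at the cut), matching short-horizon displays.
    """
    t = df[time_col].astype(float).values
    e = df[event_col].astype(bool).values
    if max_years is not None:
        e = e & (t <= max_years)
        t = np.minimum(t, max_years)
    return {
        lev: km_estimate(t[df[group_col].values == lev], e[df[group_col].values == lev])
        for lev in pd.unique(df[group_col])
    }
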