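"""Sample-size and power arithmetic for the 1:M matched case-control design.

Covers the study-design reasoning used when nesting a matched
case-control comparison of a binary molecular exposure inside a
surveillance cohort: weighted null prevalences from morphology strata,
shifting a null prevalence pair to a target odds ratio under a
mean-preserving constraint, a two-proportion normal-approximation power
formula (pooled variance by default), and a simulation check that draws
matched sets and rejects via the conditional score test.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from .clogit import score_test
from .exceptions import ParameterError


def _check_prob(name: str, p: float, open_interval: bool = False) -> None:
    ok = 0.0 < p < 1.0 if open_interval else 0.0 <= p <= 1.0
    if not ok:
        raise ParameterError(f"{name} must lie in {'(0,1)' if open_interval else '[0,1]'}, got {p}")


def odds(p: float) -> float:
    _check_prob("p", p, open_interval=True)
    return p / (1.0 - p)


def odds_ratio(p1: float, p0: float) -> float:
    """Odds ratio between two exposure prevalences."""
    return odds(p1) / odds(p0)


def expected_prevalence(weights: tuple[float, float], prevalences: tuple[float, float]) -> float:
    """Weighted mixture prevalence w1·p1 + w2·p2 (weights must sum to 1)."""
    w1, w2 = weights
    p1, p2 = prevalences
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ParameterError(f"weights must sum to 1, got {w1 + w2}")
    for name, p in (("w1", w1), ("w2", w2), ("p1", p1), ("p2", p2)):
        _check_prob(name, p)
    return w1 * p1 + w2 * p2


def shift_to_target_or(
    p_case0: float,
    p_ctrl0: float,
    target_or: float,
    constraint: str = "preserve_arithmetic_mean",
    M: int = 2,
) -> tuple[float, float]:
    """Shift a null prevalence pair so its odds ratio equals ``target_or``.

    The case prevalence moves up and the control prevalence down (for
    target_or > 1) while a mean is preserved: the arithmetic mean
    (p_case + p_ctrl)/2 under ``preserve_arithmetic_mean``, or the
    size-weighted mean (p_case + M·p_ctrl)/(1+M) under
    ``preserve_weighted_mean``.  Solved by root-finding on the control
    prevalence; both returned values lie in (0, 1) and satisfy the
    constraints to 1e-10.
    """
    for name, p in (("p_case0", p_case0), ("p_ctrl0", p_ctrl0)):
        _check_prob(name, p, open_interval=True)
    if target_or <= 0:
        raise ParameterError("target_or must be positive")
    if constraint == "preserve_arithmetic_mean":
        w = 0.5
    elif constraint == "preserve_weighted_mean":
        w = M / (M + 1.0)
    else:
        raise ParameterError(f"unknown constraint {constraint!r}")
    mean = (1.0 - w) * p_case0 + w * p_ctrl0

    def p_case_of(p_ctrl: float) -> float:
        return (mean - w * p_ctrl) / (1.0 - w)

    def f(p_ctrl: float) -> float:
        pc = p_case_of(p_ctrl)
        return math.log(odds_ratio(pc, p_ctrl)) - math.log(target_or)

    eps = 1e-12
    # p_ctrl must keep p_case inside (0, 1)
    lo = max(eps, (mean - (1.0 - w) * (1.0 - eps)) / w)
    hi = min(1.0 - eps, mean / w)
    try:
        sol = optimize.brentq(f, lo + eps, hi - eps, xtol=1e-14, rtol=8.9e-16)
    except ValueError as exc:
        raise ParameterError(
            f"no prevalence pair in (0,1) attains OR={target_or} under {constraint}"
        ) from exc
    p_ctrl = float(sol)
    p_case = float(p_case_of(p_ctrl))
    return p_case, p_ctrl


def analytic_power(
    p_case: float,
    p_ctrl: float,
    n_cases: int,
    n_controls: int | None = None,
    M: int = 2,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> float:
    """Two-proportion normal-approximation power at two-sided level ``alpha``.

    With the pooled variant (default) the null standard error
    SE0 = sqrt(p̄(1−p̄)(1/n1 + 1/n0)), p̄ the size-weighted mean prevalence,
    is used both for the critical value and for the power evaluation:
    power = Φ(|p_case − p_ctrl|/SE0 − z_{1−α/2}).  The ``unpooled``
    variant evaluates power under the alternative-variance standard error
    SE1 = sqrt(p1 q1/n1 + p0 q0/n0):
    power = Φ((|Δ| − z·SE0)/SE1).
    """
    for name, p in (("p_case", p_case), ("p_ctrl", p_ctrl)):
        _check_prob(name, p, open_interval=True)
    _check_prob("alpha", alpha, open_interval=True)
    if n_cases < 2:
        raise ParameterError("n_cases must be at least 2")
    n1 = float(n_cases)
    n0 = float(n_controls) if n_controls is not None else M * n1
    if n0 < 2:
        raise ParameterError("need at least 2 controls")
    pbar = (n1 * p_case + n0 * p_ctrl) / (n1 + n0)
    se0 = math.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = abs(p_case - p_ctrl)
    if variant == "pooled":
        return float(stats.norm.cdf(delta / se0 - z))
    if variant == "unpooled":
        se1 = math.sqrt(p_case * (1 - p_case) / n1 + p_ctrl * (1 - p_ctrl) / n0)
        return float(stats.norm.cdf((delta - z * se0) / se1))
    raise ParameterError(f"unknown variant {variant!r}")


def simulate_matched_exposure(
    p_case: float, p_ctrl: float, n_sets: int, M: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw 1:M matched sets with independent Bernoulli exposures.

    Returns (x, y, groups) arrays ready for the conditional-logistic
    routines: each set has one case with exposure probability ``p_case``
    and M controls with probability ``p_ctrl``.
    """
    K = M + 1
    x = np.empty(n_sets * K)
    y = np.zeros(n_sets * K, dtype=bool)
    y[::K] = True
    x[::K] = rng.random(n_sets) < p_case
    ctrl = (rng.random((n_sets, M)) < p_ctrl).astype(float)
    for m in range(M):
        x[m + 1 :: K] = ctrl[:, m]
    groups = np.repeat(np.arange(n_sets), K)
    return x, y, groups


def simulate_power(
    p_case: float,
    p_ctrl: float,
    n_cases: int,
    M: int = 2,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo power of the conditional score test for the 1:M design.

    Returns the rejection fraction and its binomial standard error.
    Sets in which the exposure does not vary carry no information; a
    replicate with no informative set counts as a non-rejection.
    """
    if reps < 100:
        raise ParameterError("reps must be at least 100")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        x, y, groups = simulate_matched_exposure(p_case, p_ctrl, n_cases, M, rng)
        try:
            _, p = score_test(x, y, groups)
        except Exception:
            continue
        if p < alpha:
            rejections += 1
    est = rejections / reps
    return est, math.sqrt(max(est * (1.0 - est), 1.0 / reps) / reps)


def required_n_for_proportion_se(p: float, se: float) -> float:
    """Sample size giving standard error ``se`` for a prevalence ``p`` (n = p(1−p)/se²)."""
    _check_prob("p", p, open_interval=True)
    if se <= 0:
        raise ParameterError("se must be positive")
    return p * (1.0 - p) / se**2


def design_report(
    weights_case: tuple[float, float] = (0.62, 0.38),
    weights_control: tuple[float, float] = (0.46, 0.54),
    weights_cohort: tuple[float, float] = (0.48, 0.52),
    prevalence_given_AA: float = 0.25,
    prevalence_given_nAA: float = 0.03,
    target_or: float = 3.0,
    alpha: float = 0.05,
    n_cases: int = 69,
    n_controls: int = 137,
    M: int = 2,
    simulate: bool = False,
    reps: int = 2000,
    seed: int = 0,
) -> dict:
    """Full design report: weighted null prevalences, the OR-shifted pair,
    and analytic (optionally simulated) power for the stated sample sizes."""
    prevs = (prevalence_given_AA, prevalence_given_nAA)
    p_cohort = expected_prevalence(weights_cohort, prevs)
    p_case0 = expected_prevalence(weights_case, prevs)
    p_ctrl0 = expected_prevalence(weights_control, prevs)
    p_case, p_ctrl = shift_to_target_or(p_case0, p_ctrl0, target_or)
    report = {
        "null_prevalence_cohort": p_cohort,
        "null_prevalence_cases": p_case0,
        "null_prevalence_controls": p_ctrl0,
        "shifted_prevalence_cases": p_case,
        "shifted_prevalence_controls": p_ctrl,
        "target_or": target_or,
        "achieved_or": odds_ratio(p_case, p_ctrl),
        "n_cases": n_cases,
        "n_controls": n_controls,
        "alpha": alpha,
        "analytic_power_pooled": analytic_power(p_case, p_ctrl, n_cases, n_controls, M, alpha),
        "analytic_power_unpooled": analytic_power(
            p_case, p_ctrl, n_cases, n_controls, M, alpha, variant="unpooled"
        ),
        "prevalence_se_helper": {
            "n_for_se_2.5pct_at_25pct": required_n_for_proportion_se(0.25, 0.025),
            "n_for_se_1.25pct_at_3pct": required_n_for_proportion_se(0.03, 0.0125),
        },
    }
    if simulate:
        est, mc_se = simulate_power(p_case, p_ctrl, n_cases, M, alpha, reps, seed)
        report["simulated_power"] = est
        report["simulated_power_mc_se"] = mc_se
    return report
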