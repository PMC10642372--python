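"""Conditional logistic regression for 1:M matched case-control sets.

The conditional likelihood for a matched set with one case eliminates the
per-set intercept: with covariate rows x_j for the members of set s and
the case indexed c(s),

    loglik(beta) = sum_s [ x_{c(s)}·beta − log sum_{j in s} exp(x_j·beta) ].

This module implements the likelihood, its exact gradient and Hessian
(numerically stabilised by per-set max subtraction), Newton-Raphson
fitting with step halving, Wald confidence intervals, a 1-df score test
(which for a binary exposure reduces to the Cochran-Mantel-Haenszel
statistic without continuity correction), and a matched concordance
statistic (Harrell's C restricted to within-set case-control pairs).

Data are passed as a dense covariate matrix ``X`` (one row per set
member), a boolean case indicator ``y`` (exactly one case per set) and an
integer ``groups`` vector; rows of a set must be contiguous.  The
``build_design`` helper assembles ``X`` from a covariate table and a
declarative list of terms (numeric, indicator, interaction, combined
categorical), mirroring the model specifications of matched case-control
reports.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigError,
    ConvergenceError,
    DataError,
    ParameterError,
    SeparationError,
)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# data preparation


def _group_starts(groups: np.ndarray) -> np.ndarray:
    if len(groups) == 0:
        raise DataError("empty data")
    change = np.flatnonzero(np.diff(groups)) + 1
    return np.concatenate([[0], change])


def _validate(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    groups = np.asarray(groups)
    if X.ndim != 2 or len(X) != len(y) or len(y) != len(groups):
        raise DataError("X, y and groups must have matching first dimensions")
    if np.isnan(X).any():
        raise DataError("missing covariate values")
    starts = _group_starts(groups)
    cases_per_set = np.add.reduceat(y.astype(int), starts)
    if (cases_per_set != 1).any():
        bad = int(np.flatnonzero(cases_per_set != 1)[0])
        raise DataError(f"every matched set needs exactly one case (set index {bad})")
    return starts


def informative_sets(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Boolean mask over sets: does any covariate vary within the set?"""
    X = np.asarray(X, dtype=float)
    starts = _group_starts(np.asarray(groups))
    sizes = np.diff(np.append(starts, len(groups)))
    firsts = np.repeat(X[starts], sizes, axis=0)
    differs = (X != firsts).any(axis=1)
    return np.add.reduceat(differs, starts) > 0


# ---------------------------------------------------------------------------
# likelihood


def conditional_loglik(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Value, gradient and Hessian of the conditional log-likelihood."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    starts = _validate(X, y, groups)
    sizes = np.diff(np.append(starts, len(X)))

    eta = X @ beta
    set_max = np.maximum.reduceat(eta, starts)
    eta_c = eta - np.repeat(set_max, sizes)
    expd = np.exp(eta_c)
    denom = np.add.reduceat(expd, starts)
    lse = np.log(denom) + set_max
    value = float(eta[np.asarray(y, bool)].sum() - lse.sum())

    w = expd / np.repeat(denom, sizes)  # within-set probabilities
    grad = X[np.asarray(y, bool)].sum(axis=0) - X.T @ w
    wX = w[:, None] * X
    S = np.add.reduceat(wX, starts, axis=0)  # per-set E[x]
    hess = -(X.T @ wX - S.T @ S)
    return value, grad, hess


@dataclass
class CLogitFit:
    """Result of a conditional-logistic fit."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool
    n_sets: int
    n_informative_sets: int
    score_chi2: float | None = None

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def conf_int(self) -> np.ndarray:
        with np.errstate(over="ignore"):  # huge SEs (sparse strata) -> upper bound inf
            lo = np.exp(self.beta - Z95 * self.se)
            hi = np.exp(self.beta + Z95 * self.se)
        return np.column_stack([lo, hi])

    @property
    def z_values(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "OR": self.odds_ratio,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "z": self.z_values,
                "p": self.p_values,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def fit_clogit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_bound: float = 10.0,
) -> CLogitFit:
    """Newton-Raphson maximisation of the conditional likelihood.

    Convergence: max |gradient| < ``tol``.  Steps that do not improve the
    log-likelihood are halved (up to 20 times).  Complete separation is
    declared, naming the covariate with the largest |coefficient|, when
    ‖beta‖∞ exceeds ``separation_bound`` while the gradient norm is not
    shrinking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    starts = _validate(X, y, groups)
    p = X.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]

    info_mask = informative_sets(X, groups)
    n_sets = len(starts)
    n_info = int(info_mask.sum())
    if n_info == 0:
        raise DataError("no informative sets: covariates constant within every set")
    # a covariate with zero within-set variation everywhere carries no information
    sizes = np.diff(np.append(starts, len(X)))
    firsts = np.repeat(X[starts], sizes, axis=0)
    varies = (X != firsts).any(axis=0)
    if not varies.all():
        dead = [names[j] for j in np.flatnonzero(~varies)]
        raise DataError(f"covariates constant within every set: {dead}")

    beta = np.zeros(p)
    ll, grad, hess = conditional_loglik(beta, X, y, groups)
    ll0 = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = np.max(np.abs(grad))
        if gnorm < tol:
            converged = True
            break
        # a coefficient drifting past the bound before the gradient vanishes
        # means the conditional MLE is infinite (complete or quasi-complete
        # separation): the likelihood keeps increasing along that axis
        if np.max(np.abs(beta)) > separation_bound:
            raise SeparationError(names[int(np.argmax(np.abs(beta)))])
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta, new = beta + step, None
        for _ in range(20):
            new = conditional_loglik(new_beta, X, y, groups)
            if new[0] >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        beta, (ll, grad, hess) = new_beta, new
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
        elif np.max(np.abs(beta)) > separation_bound:
            raise SeparationError(names[int(np.argmax(np.abs(beta)))])

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CLogitFit(
        names=list(names),
        beta=beta,
        se=se,
        loglik=ll,
        loglik_null=ll0,
        iterations=it,
        converged=converged,
        n_sets=n_sets,
        n_informative_sets=n_info,
    )


def score_test(
    x: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """1-df conditional score test of no effect for a single covariate.

    U(0) = Σ_s (x_case − x̄_s); I(0) = Σ_s within-set variance of x under
    the uniform distribution over set members.  For a binary exposure this
    equals the Cochran-Mantel-Haenszel statistic (no continuity
    correction) over the per-set 2×2 strata.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=bool)
    _, grad, hess = conditional_loglik(np.zeros(1), x, y, groups)
    info = float(-hess[0, 0])
    if info <= 0:
        raise DataError("zero information: exposure constant within every set")
    chi2 = float(grad[0] ** 2 / info)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def matched_concordance(
    linear_predictor: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> float:
    """Fraction of within-set (case, control) pairs ranked correctly.

    A pair counts 1 when the case's linear predictor exceeds the
    control's, 0.5 on ties.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(y, dtype=bool)
    starts = _validate(np.zeros((len(lp), 1)), y, groups)
    stops = np.append(starts[1:], len(lp))
    wins = pairs = 0.0
    for a, b in zip(starts, stops):
        lp_case = lp[a:b][y[a:b]][0]
        for v in lp[a:b][~y[a:b]]:
            pairs += 1.0
            if lp_case > v:
                wins += 1.0
            elif lp_case == v:
                wins += 0.5
    return wins / pairs if pairs else float("nan")


# ---------------------------------------------------------------------------
# design matrices


@dataclass(frozen=True)
class Term:
    """One column (or column block) of a design matrix.

    kinds: ``numeric`` (use ``column`` as-is), ``indicator`` (1 when
    ``column`` equals ``level``), ``interaction`` (product of two
    previously defined terms, ``of``), ``categorical`` (joint levels of
    ``columns`` as indicators against the ``reference`` cell).
    """

    name: str
    kind: str
    column: str | None = None
    level: object | None = None
    of: tuple | None = None
    columns: tuple | None = None
    reference: tuple | None = None


def build_design(
    covariates: pd.DataFrame, terms: list[Term]
) -> tuple[np.ndarray, list]:
    """Assemble (X, column names) from a covariate table and term list."""
    cols: dict[str, np.ndarray] = {}
    names: list[str] = []

    def need(col):
        if col not in covariates.columns:
            raise ConfigError(f"covariate column {col!r} not found in covariate table")

    for t in terms:
        if t.kind == "numeric":
            need(t.column)
            cols[t.name] = covariates[t.column].astype(float).values
            names.append(t.name)
        elif t.kind == "indicator":
            need(t.column)
            cols[t.name] = (covariates[t.column] == t.level).astype(float).values
            names.append(t.name)
        elif t.kind == "interaction":
            a, b = t.of
            for ref in (a, b):
                if ref not in cols:
                    raise ParameterError(f"interaction {t.name!r} references unknown term {ref!r}")
            cols[t.name] = cols[a] * cols[b]
            names.append(t.name)
        elif t.kind == "categorical":
            for c in t.columns:
                need(c)
            joint = list(zip(*(covariates[c] for c in t.columns)))
            levels = sorted(set(joint), key=repr)
            ref = tuple(t.reference)
            if ref not in levels:
                raise ParameterError(f"reference cell {ref} absent from data for {t.name!r}")
            for lev in levels:
                if lev == ref:
                    continue
                label = f"{t.name}[" + "&".join(map(str, lev)) + "]"
                cols[label] = np.array([v == lev for v in joint], dtype=float)
                names.append(label)
        else:
            raise ParameterError(f"unknown term kind {t.kind!r}")
    X = np.column_stack([cols[n] for n in names]) if names else np.empty((len(covariates), 0))
    return X, names


def matched_arrays(
    sets_df: pd.DataFrame, covariates: pd.DataFrame, terms: list[Term]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Join a long matched-set table with covariates into fit-ready arrays.

    ``sets_df`` needs columns set_id / role / subject_id (as written by
    :func:`caerisk.matching.sets_to_frame`); ``covariates`` is indexed or
    keyed by subject id.
    """
    cov = covariates.set_index("id") if "id" in covariates.columns else covariates
    merged = sets_df.copy()
    missing = set(merged["subject_id"]) - set(cov.index)
    if missing:
        raise DataError(f"covariates missing for subjects {sorted(missing)[:5]}")
    merged = merged.join(cov, on="subject_id")
    # rows of a set must be contiguous; within-set order is irrelevant
    merged = merged.sort_values(["set_id", "role"], kind="mergesort")
    X, names = build_design(merged, terms)
    y = (merged["role"] == "case").values
    groups = pd.factorize(merged["set_id"])[0]
    return X, y, groups, names


def fit_matched(
    sets_df: pd.DataFrame,
    covariates: pd.DataFrame,
    terms: list[Term],
    **kwargs,
) -> CLogitFit:
    """Fit a conditional-logistic model directly from tables."""
    X, y, groups, names = matched_arrays(sets_df, covariates, terms)
    return fit_clogit(X, y, groups, names=names, **kwargs)
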