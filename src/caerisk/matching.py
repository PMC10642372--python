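"""Incidence-density (risk-set) matching for the nested case-control design.

Each subject who develops the outcome (a case) is matched to ``M``
controls of the same sex whose baseline age is within ±``age_window``
years and whose follow-up is at least as long as the case's event time,
i.e. controls are drawn from the case's risk set.  By default, controls
are drawn only from subjects who never develop the outcome (the study's
policy); textbook risk-set sampling, where a later case may serve as an
earlier case's control, is selectable via ``allow_future_cases``.

Cases are processed in ascending order of event time (ties broken by id):
early cases have the largest risk sets, which maximises feasibility under
sampling without replacement, and the order is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Subject
from .exceptions import DataError, ParameterError


@dataclass(frozen=True)
class MatchedSet:
    """One case with its incidence-density-sampled controls."""

    set_id: str
    case_id: str
    control_ids: tuple
    index_time_years: float


def eligible_controls(
    case: Subject,
    pool: list[Subject],
    age_window: float = 5.0,
    allow_future_cases: bool = False,
) -> list[Subject]:
    """All pool members in the case's risk set, sorted by id.

    Eligibility: same sex, |age difference| <= ``age_window`` (closed
    window, ages compared as stored), follow-up at least the case's event
    time, and not the case itself.  Unless ``allow_future_cases``, any
    subject who ever develops the outcome is excluded; otherwise subjects
    whose own event occurs strictly after the index time remain eligible.
    """
    out = []
    for s in pool:
        if s.id == case.id or s.sex != case.sex:
            continue
        if abs(s.age_at_baseline - case.age_at_baseline) > age_window:
            continue
        if s.followup_years < case.event_time_years:
            continue
        if s.event:
            if not allow_future_cases:
                continue
            if s.event_time_years <= case.event_time_years:
                continue
        out.append(s)
    return sorted(out, key=lambda s: s.id)


def match_cases(
    cohort: list[Subject],
    M: int = 2,
    age_window: float = 5.0,
    seed: int = 0,
    reuse_policy: str = "without_replacement",
    shortfall_policy: str = "drop",
    allow_future_cases: bool = False,
) -> tuple[list[MatchedSet], dict]:
    """Build 1:M matched sets by seeded uniform sampling from risk sets.

    Returns the matched sets and a report dict with counts of matched and
    dropped cases and, per dropped case, the number of eligible controls
    found.  Under ``shortfall_policy='keep'`` a case with fewer than M
    (but at least one) eligible controls yields a smaller set.
    """
    if M < 1:
        raise ParameterError("M must be at least 1")
    if reuse_policy not in ("without_replacement", "with_replacement"):
        raise ParameterError(f"unknown reuse_policy {reuse_policy!r}")
    if shortfall_policy not in ("drop", "keep"):
        raise ParameterError(f"unknown shortfall_policy {shortfall_policy!r}")
    cases = sorted(
        (s for s in cohort if s.event), key=lambda s: (s.event_time_years, s.id)
    )
    if not cases:
        raise DataError("cohort contains no cases")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    sets: list[MatchedSet] = []
    dropped: list[dict] = []
    width = len(str(len(cases)))
    for k, case in enumerate(cases):
        elig = eligible_controls(case, cohort, age_window, allow_future_cases)
        if reuse_policy == "without_replacement":
            elig = [s for s in elig if s.id not in used]
        n_found = len(elig)
        if n_found < M and shortfall_policy == "drop" or n_found == 0:
            dropped.append({"case_id": case.id, "eligible": n_found})
            continue
        take = min(M, n_found)
        idx = rng.choice(n_found, size=take, replace=False)
        chosen = tuple(elig[i].id for i in sorted(idx))
        used.update(chosen)
        sets.append(
            MatchedSet(
                set_id=f"M{k:0{width}d}",
                case_id=case.id,
                control_ids=chosen,
                index_time_years=case.event_time_years,
            )
        )
    report = {
        "n_cases": len(cases),
        "n_matched": len(sets),
        "n_dropped": len(dropped),
        "dropped": dropped,
        "M": M,
        "age_window": age_window,
        "reuse_policy": reuse_policy,
        "shortfall_policy": shortfall_policy,
        "allow_future_cases": allow_future_cases,
        "seed": seed,
    }
    return sets, report


def audit_sets(
    sets: list[MatchedSet],
    cohort: list[Subject],
    age_window: float = 5.0,
    allow_future_cases: bool = False,
) -> None:
    """Re-verify every emitted set against the eligibility rules.

    Raises :class:`DataError` on the first violation; silent when clean.
    """
    by_id = {s.id: s for s in cohort}
    for ms in sets:
        case = by_id[ms.case_id]
        if not case.event:
            raise DataError(f"set {ms.set_id}: case {case.id} has no event")
        elig_ids = {
            s.id for s in eligible_controls(case, cohort, age_window, allow_future_cases)
        }
        for cid in ms.control_ids:
            if cid == ms.case_id:
                raise DataError(f"set {ms.set_id}: case reused as control")
            if cid not in elig_ids:
                raise DataError(f"set {ms.set_id}: control {cid} fails eligibility audit")


def sets_to_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    """Long-format matched-set table: set_id, role, subject_id, index_time."""
    rows = []
    for ms in sets:
        rows.append(
            {"set_id": ms.set_id, "role": "case", "subject_id": ms.case_id,
             "index_time_years": ms.index_time_years}
        )
        for cid in ms.control_ids:
            rows.append(
                {"set_id": ms.set_id, "role": "control", "subject_id": cid,
                 "index_time_years": ms.index_time_years}
            )
    return pd.DataFrame(rows, columns=["set_id", "role", "subject_id", "index_time_years"])
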