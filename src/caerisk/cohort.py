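"""Synthetic adenoma surveillance cohorts with known ground truth.

Each generated subject carries baseline covariates (sex, age, adenoma
morphology), a true set of chromosome-arm copy-number events consistent
with the molecular-risk prevalences requested, and a time-to-event
outcome for metachronous colorectal cancer (me-CRC) under an exponential
hazard whose log is linear in the covariates.  Bin-level log2-ratio
profiles can then be generated from the true arm events, so the whole
classification → matching → regression pipeline can be exercised with
the truth known.

Defaults emulate the structure of a national surveillance adenoma cohort:
50.5% advanced adenomas (AA), molecular high-risk (≥2 CAEs) in 31.8% of
AAs and 10.3% of non-AAs, odds/hazard effects of about 2.9 for AA and
2.3 for ≥3 arm losses, and administrative censoring giving a median
follow-up near 13 years.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .arms import ArmMap, CAE_GAIN_ARMS, CAE_LOSS_ARMS
from .copynumber import (
    ArmEventSet,
    CopyNumberProfile,
    GAIN,
    LOSS,
    NEUTRAL,
    classify_molecular,
)
from .exceptions import DataError, ParameterError

_SEXES = ("male", "female")
_MORPH = ("advanced", "non_advanced")


@dataclass(frozen=True)
class Subject:
    """One cohort member: baseline covariates, simulation truth, outcome."""

    id: str
    sex: str
    age_at_baseline: float
    morphology: str
    true_arm_events: ArmEventSet
    followup_years: float
    event: bool
    event_time_years: float

    def __post_init__(self):
        if self.sex not in _SEXES:
            raise ParameterError(f"sex must be one of {_SEXES}")
        if self.morphology not in _MORPH:
            raise ParameterError(f"morphology must be one of {_MORPH}")
        if self.age_at_baseline < 40:
            raise ParameterError("cohort includes only subjects aged 40 or older")
        if self.event_time_years > self.followup_years + 1e-12:
            raise ParameterError("event_time_years must not exceed followup_years")
        if not self.event and self.event_time_years != self.followup_years:
            raise ParameterError("censored subjects must have event_time == followup")


@dataclass(frozen=True)
class CohortParams:
    """Design parameters of the synthetic cohort.

    ``log_or`` maps covariate names to log odds-/hazard-ratios applied to
    the exponential event rate.  Supported names: ``advanced`` and the
    molecular flags ``high_cae``/``high_cna``/``high_gain``/``high_loss``
    (0/1 indicators) and ``age`` (per year, centred at the age mean).
    """

    n_subjects: int = 521
    p_advanced: float = 0.505
    p_cae_high_given_AA: float = 0.318
    p_cae_high_given_nAA: float = 0.103
    log_or: dict = field(
        default_factory=lambda: {
            "advanced": math.log(2.9),
            "high_loss": math.log(2.3),
        }
    )
    baseline_hazard: float = 0.01  # events per person-year at reference covariates
    censoring_horizon_years: float = 23.0
    censoring_min_years: float = 3.0  # staggered entry: censor ~ U(min, horizon)
    age_distribution: tuple = (69.0, 10.0, 40.0)  # mean, sd, min (truncated normal)
    sex_ratio: float = 0.44  # probability male
    seed: int = 0

    # secondary structure of the arm-event truth
    p_single_cae_low: float = 0.25  # P(exactly one CAE | molecular low-risk)
    p_background_alteration: float = 0.03  # per non-CAE arm
    cae_count_weights: tuple = (0.55, 0.30, 0.15)  # for 2, 3, 4 CAEs when high

    def validate(self) -> None:
        probs = {
            "p_advanced": self.p_advanced,
            "p_cae_high_given_AA": self.p_cae_high_given_AA,
            "p_cae_high_given_nAA": self.p_cae_high_given_nAA,
            "sex_ratio": self.sex_ratio,
            "p_single_cae_low": self.p_single_cae_low,
            "p_background_alteration": self.p_background_alteration,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        if self.n_subjects <= 0:
            raise ParameterError("n_subjects must be positive")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be positive")
        if not 0 <= self.censoring_min_years <= self.censoring_horizon_years:
            raise ParameterError("need 0 <= censoring_min_years <= censoring_horizon_years")


_CAE_EVENTS = [(a, GAIN) for a in CAE_GAIN_ARMS] + [(a, LOSS) for a in CAE_LOSS_ARMS]


def _sample_arm_events(
    rng: np.random.Generator, high: bool, params: CohortParams, arms: list[str], sid: str
) -> ArmEventSet:
    status = {a: NEUTRAL for a in arms}
    if high:
        k = rng.choice([2, 3, 4], p=np.asarray(params.cae_count_weights) / sum(params.cae_count_weights))
    else:
        k = int(rng.random() < params.p_single_cae_low)
    for idx in rng.choice(len(_CAE_EVENTS), size=k, replace=False):
        arm, direction = _CAE_EVENTS[idx]
        if arm not in status:
            raise DataError(f"CAE arm {arm} missing from arm map")
        status[arm] = direction
    cae_arms = {a for a, _ in _CAE_EVENTS}
    for arm in arms:
        if arm in cae_arms:
            continue
        if rng.random() < params.p_background_alteration:
            status[arm] = GAIN if rng.random() < 0.5 else LOSS
    return ArmEventSet(sample_id=sid, status=status)


def _covariate_value(name: str, subject_row: dict, params: CohortParams) -> float:
    if name == "advanced":
        return 1.0 if subject_row["morphology"] == "advanced" else 0.0
    if name == "age":
        return subject_row["age_at_baseline"] - params.age_distribution[0]
    if name in ("high_cae", "high_cna", "high_gain", "high_loss"):
        return 1.0 if subject_row[name] else 0.0
    raise ParameterError(f"unknown log_or covariate {name!r}")


def generate_cohort(params: CohortParams, arm_map: ArmMap | None = None) -> list[Subject]:
    """Draw a reproducible cohort under the given design parameters.

    Morphology and molecular-risk truth are sampled first (the ≥2-CAE rule
    applied to the true arm events reproduces the conditional prevalences);
    event times then follow an exponential distribution with rate
    ``baseline_hazard * exp(Σ log_or·x)`` and are administratively censored
    at a time drawn uniformly between ``censoring_min_years`` and
    ``censoring_horizon_years``.
    """
    params.validate()
    if arm_map is None:
        arm_map = ArmMap.hg38()
    arms = arm_map.eligible_arms()
    rng = np.random.default_rng(params.seed)
    mean, sd, lo = params.age_distribution

    subjects: list[Subject] = []
    width = len(str(params.n_subjects))
    for i in range(params.n_subjects):
        sid = f"S{i:0{width}d}"
        sex = "male" if rng.random() < params.sex_ratio else "female"
        age = float(lo - 1)
        while age < lo:  # truncated normal by rejection
            age = rng.normal(mean, sd)
        advanced = rng.random() < params.p_advanced
        p_high = params.p_cae_high_given_AA if advanced else params.p_cae_high_given_nAA
        high = rng.random() < p_high
        events = _sample_arm_events(rng, high, params, arms, sid)
        flags = classify_molecular(events).as_dict()
        row = {
            "morphology": "advanced" if advanced else "non_advanced",
            "age_at_baseline": age,
            **flags,
        }
        log_rate = math.log(params.baseline_hazard) + sum(
            b * _covariate_value(name, row, params) for name, b in params.log_or.items()
        )
        t_event = rng.exponential(1.0 / math.exp(log_rate))
        censor = rng.uniform(params.censoring_min_years, params.censoring_horizon_years)
        event = t_event <= censor
        t = t_event if event else censor
        subjects.append(
            Subject(
                id=sid,
                sex=sex,
                age_at_baseline=round(age, 2),
                morphology=row["morphology"],
                true_arm_events=events,
                followup_years=round(t, 4),
                event=bool(event),
                event_time_years=round(t, 4),
            )
        )
    return subjects


def generate_profiles(
    subjects: list[Subject],
    bin_width: int = 100_000,
    noise_sd: float = 0.05,
    seed: int = 0,
    gain_mean: float = 0.58,
    loss_mean: float = -1.0,
    arm_map: ArmMap | None = None,
) -> list[CopyNumberProfile]:
    """Bin-level log2-ratio profiles consistent with each subject's truth.

    Bins tile every arm of the arm map (0-based half-open, the last bin of
    an arm truncated at the arm end); each bin's log2 ratio is the segment
    mean implied by the subject's true arm status (``gain_mean``,
    ``loss_mean`` or 0) plus Gaussian noise of sd ``noise_sd``.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if arm_map is None:
        arm_map = ArmMap.hg38()
    rng = np.random.default_rng(seed)

    chroms, starts, ends, arm_names = [], [], [], []
    for row in arm_map.table.itertuples():
        s = np.arange(row.start, row.end, bin_width, dtype=np.int64)
        e = np.minimum(s + bin_width, row.end)
        chroms.append(np.full(len(s), row.chrom, dtype=object))
        starts.append(s)
        ends.append(e)
        arm_names.append(np.full(len(s), row.name, dtype=object))
    chrom = np.concatenate(chroms)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    arm = np.concatenate(arm_names)

    means_by_status = {GAIN: gain_mean, LOSS: loss_mean, NEUTRAL: 0.0}
    profiles = []
    for subj in subjects:
        unknown = set(subj.true_arm_events.status) - set(arm_map.arm_names)
        if unknown:
            raise DataError(f"subject {subj.id}: unknown arms in truth: {sorted(unknown)}")
        seg_mean = np.array(
            [means_by_status[subj.true_arm_events.status.get(a, NEUTRAL)] for a in arm]
        )
        lr = seg_mean if noise_sd == 0 else seg_mean + rng.normal(0.0, noise_sd, size=len(arm))
        bins = pd.DataFrame(
            {"chrom": chrom, "start": start, "end": end, "log2ratio": lr}
        )
        profiles.append(CopyNumberProfile(sample_id=subj.id, bins=bins, build=arm_map.build))
    return profiles


def cohort_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Flatten subjects to one row each, including truth-derived risk flags."""
    rows = []
    for s in subjects:
        flags = classify_molecular(s.true_arm_events).as_dict()
        rows.append(
            {
                "id": s.id,
                "sex": s.sex,
                "age_at_baseline": s.age_at_baseline,
                "morphology": s.morphology,
                "followup_years": s.followup_years,
                "event": s.event,
                "event_time_years": s.event_time_years,
                "cae_count": s.true_arm_events.cae_count,
                "n_gains": s.true_arm_events.n_gains,
                "n_losses": s.true_arm_events.n_losses,
                "n_cna": s.true_arm_events.n_cna,
                **flags,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(subjects: list[Subject], path) -> None:
    cohort_to_frame(subjects).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "sex", "age_at_baseline", "morphology", "followup_years", "event", "event_time_years"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"cohort table missing columns {sorted(missing)}")
    return df
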