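"""Arm-level copy-number classification of binned profiles.

The workflow mirrors standard low-coverage WGS copy-number analysis of
adenomas: per-bin log2 ratios are thresholded into loss / normal / gain
calls, calls are aggregated to chromosome-arm events, and each sample is
scored for cancer-associated events (CAEs: gains of 8q, 13q, 20q; losses
of 8p, 15q, 17p, 18q) and overall alteration burden.  Four binary
high-risk flags are derived:

* ``high_cae``  — ≥2 CAEs (the molecular high-risk definition),
* ``high_cna``  — ≥3 altered arms of any direction,
* ``high_gain`` — ≥3 arm gains,
* ``high_loss`` — ≥3 arm losses.

A deterministic threshold caller replaces mixture-model calling: it is
exact at the noise levels the synthetic profiles carry and keeps the
pipeline reproducible; thresholds are configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arms import ArmMap, CAE_GAIN_ARMS, CAE_LOSS_ARMS, cae_count as _cae_count
from .exceptions import DataError, ParameterError

GAIN, LOSS, NORMAL, NEUTRAL = "gain", "loss", "normal", "neutral"

BIN_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class CopyNumberProfile:
    """One sample's ordered, non-overlapping genomic bins.

    ``bins`` must contain chrom/start/end (0-based half-open) and at least
    one of ``log2ratio`` or ``call``.
    """

    sample_id: str
    bins: pd.DataFrame
    build: str = "hg38"

    def __post_init__(self):
        b = self.bins
        missing = [c for c in BIN_COLUMNS if c not in b.columns]
        if missing:
            raise DataError(f"profile {self.sample_id}: missing columns {missing}")
        if "log2ratio" not in b.columns and "call" not in b.columns:
            raise DataError(f"profile {self.sample_id}: need log2ratio or call per bin")
        if len(b) == 0:
            raise DataError(f"profile {self.sample_id}: empty bin table")
        if (b["end"].values <= b["start"].values).any():
            raise DataError(f"profile {self.sample_id}: bins with end <= start")
        srt = b.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        same = srt["chrom"].values[1:] == srt["chrom"].values[:-1]
        if (same & (srt["start"].values[1:] < srt["end"].values[:-1])).any():
            raise DataError(f"profile {self.sample_id}: overlapping bins")
        object.__setattr__(self, "bins", srt)

    @property
    def has_calls(self) -> bool:
        return "call" in self.bins.columns

    def __len__(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class ArmEventSet:
    """Per-arm gain/loss/neutral status of one sample, with burden counts."""

    sample_id: str
    status: dict = field(default_factory=dict)

    @property
    def n_gains(self) -> int:
        return sum(1 for v in self.status.values() if v == GAIN)

    @property
    def n_losses(self) -> int:
        return sum(1 for v in self.status.values() if v == LOSS)

    @property
    def n_cna(self) -> int:
        return self.n_gains + self.n_losses

    @property
    def cae_count(self) -> int:
        return _cae_count(self.status)


@dataclass(frozen=True)
class MolecularRiskCall:
    high_cae: bool
    high_cna: bool
    high_gain: bool
    high_loss: bool

    def as_dict(self) -> dict[str, bool]:
        return {
            "high_cae": self.high_cae,
            "high_cna": self.high_cna,
            "high_gain": self.high_gain,
            "high_loss": self.high_loss,
        }


def call_bins(
    profile: CopyNumberProfile,
    gain_threshold: float = 0.10,
    loss_threshold: float = -0.10,
) -> CopyNumberProfile:
    """Threshold per-bin log2 ratios into loss / normal / gain calls.

    A bin is a gain if log2ratio >= ``gain_threshold``, a loss if
    <= ``loss_threshold``, otherwise normal.  Idempotent: existing calls
    are recomputed from the ratios when ratios are present, and kept as-is
    for bins without a ratio.
    """
    if not (loss_threshold < 0 < gain_threshold):
        raise ParameterError("need loss_threshold < 0 < gain_threshold")
    b = profile.bins.copy()
    if "log2ratio" not in b.columns or b["log2ratio"].isna().all():
        if profile.has_calls:
            return profile
        raise DataError(f"profile {profile.sample_id}: no log2ratio to call from")
    if b["log2ratio"].isna().any():
        if not profile.has_calls:
            raise DataError(f"profile {profile.sample_id}: missing log2ratio values")
        ratio_ok = b["log2ratio"].notna().values
    else:
        ratio_ok = np.ones(len(b), dtype=bool)
    lr = b["log2ratio"].values
    calls = np.where(lr >= gain_threshold, GAIN, np.where(lr <= loss_threshold, LOSS, NORMAL))
    if "call" in b.columns:
        calls = np.where(ratio_ok, calls, b["call"].values)
    b["call"] = calls
    return replace(profile, bins=b)


def derive_arm_events(
    profile: CopyNumberProfile,
    arm_map: ArmMap | None = None,
    min_fraction: float = 0.5,
) -> ArmEventSet:
    """Aggregate per-bin calls into per-arm gain/loss/neutral events.

    An arm is called gained (lost) when at least ``min_fraction`` of its
    covered bins are gain (loss) calls; if both directions pass, the
    larger fraction wins and an exact tie is neutral.  Arms with no bins
    in the profile are neutral.
    """
    if not (0.5 <= min_fraction <= 1.0):
        raise ParameterError("min_fraction must lie in [0.5, 1]")
    if arm_map is None:
        arm_map = ArmMap.hg38()
    if not profile.has_calls:
        raise DataError(f"profile {profile.sample_id}: bins are uncalled; run call_bins first")
    b = profile.bins
    arm_of = arm_map.assign_bins(b["chrom"], b["start"], b["end"])
    status = {name: NEUTRAL for name in arm_map.eligible_arms()}
    sub = pd.DataFrame({"arm": arm_of.values, "call": b["call"].values}).dropna(subset=["arm"])
    for arm, grp in sub.groupby("arm", sort=False):
        if arm not in status:
            continue
        n = len(grp)
        f_gain = (grp["call"] == GAIN).sum() / n
        f_loss = (grp["call"] == LOSS).sum() / n
        if f_gain >= min_fraction or f_loss >= min_fraction:
            if f_gain > f_loss:
                status[arm] = GAIN
            elif f_loss > f_gain:
                status[arm] = LOSS
            # exact tie stays neutral
    return ArmEventSet(sample_id=profile.sample_id, status=status)


def count_cae(events: ArmEventSet) -> int:
    """Number of the seven direction-specific cancer-associated events present."""
    return events.cae_count


def classify_molecular(
    events: ArmEventSet,
    cae_threshold: int = 2,
    burden_threshold: int = 3,
) -> MolecularRiskCall:
    """Derive the four binary high-risk flags from an arm-event set."""
    return MolecularRiskCall(
        high_cae=events.cae_count >= cae_threshold,
        high_cna=events.n_cna >= burden_threshold,
        high_gain=events.n_gains >= burden_threshold,
        high_loss=events.n_losses >= burden_threshold,
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used in the report tables)."""
    factor = 10.0**decimals
    scaled = x * factor
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor


def crosstab_morphology_molecular(
    subjects: pd.DataFrame,
    flag: str = "high_cae",
    morphology_col: str = "morphology",
) -> pd.DataFrame:
    """Morphology × molecular-risk crosstab with column percentages.

    ``subjects`` needs one row per subject with a morphology label
    (``advanced`` / ``non_advanced``) and a boolean risk flag column.
    Percentages are within-column (of AA, of non-AA, of total), one
    decimal, rounded half away from zero.
    """
    for col in (morphology_col, flag):
        if col not in subjects.columns or subjects[col].isna().any():
            raise DataError(f"every subject needs a non-missing {col!r} value")
    morph = subjects[morphology_col].astype(str)
    risk = subjects[flag].astype(bool).map({True: "high", False: "low"})
    counts = pd.crosstab(risk, morph).reindex(
        index=["high", "low"], columns=["advanced", "non_advanced"], fill_value=0
    )
    counts["total"] = counts.sum(axis=1)
    counts.loc["total"] = counts.sum(axis=0)
    pct = counts.div(counts.loc["total"], axis=1) * 100.0
    pct = pct.map(lambda v: round_half_away(v, 1))
    out = counts.astype(int).astype(str) + " (" + pct.map(lambda v: f"{v:.1f}") + ")"
    out.index.name = "molecular_risk"
    out.columns.name = None
    out.attrs["counts"] = counts
    out.attrs["percent"] = pct
    return out


# ---------------------------------------------------------------------------
# plain-text I/O


def read_bin_table(path, sample_id: str, build: str = "hg38") -> CopyNumberProfile:
    """Read a tab-delimited bin table (chrom, start, end, log2ratio[, call])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return CopyNumberProfile(sample_id=sample_id, bins=df, build=build)


def write_bin_table(profile: CopyNumberProfile, path) -> None:
    profile.bins.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path) -> list[CopyNumberProfile]:
    """Read a SEG file (sample, chrom, start, end, seg.mean) into profiles.

    Each segment becomes one 'bin'; downstream arm aggregation treats the
    file's segments as the resolution unit.
    """
    df = pd.read_csv(path, sep="\t", dtype={1: str})
    df.columns = ["sample_id", "chrom", "start", "end", "log2ratio"] + list(df.columns[5:])
    return [
        CopyNumberProfile(sample_id=sid, bins=g.drop(columns="sample_id").reset_index(drop=True))
        for sid, g in df.groupby("sample_id", sort=False)
    ]


def events_to_frame(
    events: list[ArmEventSet], calls: list[MolecularRiskCall] | None = None
) -> pd.DataFrame:
    """Tabulate arm-event sets (and optional risk calls), one row per sample."""
    rows = []
    for i, ev in enumerate(events):
        row = {
            "sample_id": ev.sample_id,
            "cae_count": ev.cae_count,
            "n_gains": ev.n_gains,
            "n_losses": ev.n_losses,
            "n_cna": ev.n_cna,
        }
        for arm, st in sorted(ev.status.items()):
            row[f"arm_{arm}"] = st
        if calls is not None:
            row.update(calls[i].as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
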