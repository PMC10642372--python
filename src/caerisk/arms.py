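"""Chromosome-arm definitions and the cancer-associated-event (CAE) catalogue.

Arms are read from a UCSC cytoBand-dialect file (tab-delimited: chrom,
start, end, band name, Giemsa stain; 0-based half-open coordinates) and
collapsed to one interval per arm, keyed by names like ``"8q"``.  A coarse
hg38 arm table (one synthetic band per arm, autosomes only) ships with the
package; any cytoBand file for any build can be substituted.

The seven direction-specific CAEs are gains of 8q, 13q and 20q and losses
of 8p, 15q, 17p and 18q; two or more of them define a molecular high-risk
adenoma.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ConfigError, DataError

#: Arm-level gains that count as cancer-associated events.
CAE_GAIN_ARMS = ("8q", "13q", "20q")
#: Arm-level losses that count as cancer-associated events.
CAE_LOSS_ARMS = ("8p", "15q", "17p", "18q")

#: Acrocentric short arms carry no reliably mappable sequence and are
#: excluded from the set of arms eligible for alteration calls.
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})

_GAIN, _LOSS, _NEUTRAL = "gain", "loss", "neutral"


def _normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


@dataclass(frozen=True)
class ArmMap:
    """Genomic intervals of chromosome arms, 0-based half-open.

    ``table`` has columns ``chrom`` (no ``chr`` prefix), ``arm`` (``p``/``q``),
    ``name`` (e.g. ``"8q"``), ``start``, ``end``.
    """

    table: pd.DataFrame
    build: str = "hg38"
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        t = self.table
        for chrom, sub in t.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ConfigError(f"overlapping arm definitions on chromosome {chrom}")
        trees = {
            chrom: IntervalTree.from_tuples(
                (row.start, row.end, row.name_) for row in sub.itertuples()
            )
            for chrom, sub in t.rename(columns={"name": "name_"}).groupby("chrom")
        }
        object.__setattr__(self, "_trees", trees)

    @classmethod
    def from_cytoband(cls, path: str | Path, build: str = "") -> "ArmMap":
        """Collapse a cytoBand-dialect file to one interval per arm."""
        bands = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "band", "stain"],
            dtype={"chrom": str, "band": str},
        )
        if bands.empty:
            raise DataError(f"no bands read from {path}")
        bands["chrom"] = bands["chrom"].map(_normalize_chrom)
        bands["arm"] = bands["band"].str[0]
        bad = ~bands["arm"].isin(["p", "q"])
        if bad.any():
            raise DataError(f"band names must start with p or q; offending rows: {bands[bad].head()}")
        agg = (
            bands.groupby(["chrom", "arm"], as_index=False)
            .agg(start=("start", "min"), end=("end", "max"))
        )
        agg["name"] = agg["chrom"] + agg["arm"]
        agg = agg[["chrom", "arm", "name", "start", "end"]]
        return cls(table=agg.reset_index(drop=True), build=build or Path(path).stem)

    @classmethod
    def hg38(cls) -> "ArmMap":
        """The packaged coarse hg38 autosomal arm map."""
        ref = resources.files("caerisk.data") / "hg38_arms_simplified.cytoband.tsv"
        with resources.as_file(ref) as path:
            return cls.from_cytoband(path, build="hg38")

    @property
    def arm_names(self) -> list[str]:
        return list(self.table["name"])

    def eligible_arms(self) -> list[str]:
        """Arms on which alteration events may be called (acrocentric p arms excluded)."""
        return [a for a in self.arm_names if a not in ACROCENTRIC_P_ARMS]

    def arm_interval(self, name: str) -> tuple[str, int, int]:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise DataError(f"unknown arm {name!r}")
        r = row.iloc[0]
        return r["chrom"], int(r["start"]), int(r["end"])

    def assign_bins(self, chrom, start, end) -> pd.Series:
        """Assign each bin to the arm containing its midpoint (NaN if none)."""
        chroms = pd.Series(chrom, dtype=str).map(_normalize_chrom)
        mids = (pd.Series(start).astype(int) + pd.Series(end).astype(int)) // 2
        out = []
        for c, m in zip(chroms, mids):
            tree = self._trees.get(c)
            hits = tree[m] if tree is not None else None
            out.append(next(iter(hits)).data if hits else None)
        return pd.Series(out, dtype=object)


def cae_count(status: dict[str, str]) -> int:
    """Number of the seven direction-specific CAEs present in an arm-status map."""
    n = sum(1 for a in CAE_GAIN_ARMS if status.get(a) == _GAIN)
    n += sum(1 for a in CAE_LOSS_ARMS if status.get(a) == _LOSS)
    return n
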