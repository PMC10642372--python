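"""End-to-end study orchestration: generate → classify → match → fit → report.

``run_study`` executes the whole nested case-control workflow from a
single declarative :class:`StudyConfig` and writes the report bundle —
cohort table, per-sample classification, morphology × molecular crosstab,
matched-set summary, univariate and multivariate conditional-logistic
fits, subgroup contrasts, time-window-stratified fits, Kaplan-Meier
curves and log-rank results — plus a manifest recording the seed and a
hash of the configuration.  Identical config and seed reproduce the
bundle byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arms import ArmMap
from .clogit import Term, fit_matched, matched_arrays, matched_concordance
from .cohort import CohortParams, cohort_to_frame, generate_cohort, generate_profiles, read_cohort
from .copynumber import (
    call_bins,
    classify_molecular,
    crosstab_morphology_molecular,
    derive_arm_events,
    events_to_frame,
    round_half_away,
)
from .exceptions import CaeriskError, ConfigError, ConvergenceError
from .matching import audit_sets, match_cases, sets_to_frame
from .survival import DEFAULT_WINDOWS, km_by_group, logrank_test, stratified_window_or, window_label

log = logging.getLogger("caerisk")

_FLAGS = ["high_cae", "high_cna", "high_gain", "high_loss"]


@dataclass
class StudyConfig:
    """Declarative description of one study run."""

    seed: int = 0
    outdir: str = "study_out"
    cohort_file: str | None = None  # pre-existing cohort table; else synthetic
    cohort: dict = field(default_factory=dict)  # CohortParams overrides
    bin_width: int = 1_000_000
    noise_sd: float = 0.05
    gain_threshold: float = 0.10
    loss_threshold: float = -0.10
    min_fraction: float = 0.5
    M: int = 2
    age_window: float = 5.0
    reuse_policy: str = "without_replacement"
    shortfall_policy: str = "drop"
    allow_future_cases: bool = False
    univariate: list = field(
        default_factory=lambda: ["age", "advanced"] + _FLAGS
    )
    multivariate: list = field(
        default_factory=lambda: [
            ["age", "advanced", "high_cae"],
            ["age", "advanced", "high_loss"],
        ]
    )
    subgroup_flag: str = "high_cae"
    windows: list = field(default_factory=lambda: [list(w) for w in DEFAULT_WINDOWS])
    window_exposures: list = field(default_factory=lambda: ["high_cae", "high_loss", "advanced"])
    km_truncate_years: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _term_for(name: str) -> Term:
    if name == "age":
        return Term(name="age", kind="numeric", column="age_at_baseline")
    if name == "advanced":
        return Term(name="advanced", kind="indicator", column="morphology", level="advanced")
    if name in _FLAGS:
        return Term(name=name, kind="indicator", column=name, level=True)
    raise ConfigError(f"unknown model covariate {name!r}")


def _stage_seed(root: int, index: int) -> int:
    child = np.random.SeedSequence(root).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def _fit_row(name: str, fit) -> dict:
    s = fit.summary()
    rows = []
    for cov, r in s.iterrows():
        rows.append(
            {
                "model": name,
                "covariate": cov,
                "OR": r["OR"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "p": r["p"],
                "coef": r["coef"],
                "se": r["se"],
                "n_sets": fit.n_sets,
                "converged": fit.converged,
            }
        )
    return rows


def _pct(n: int, total: int) -> str:
    return f"{n} ({round_half_away(100.0 * n / total, 1):.1f})" if total else f"{n} (0.0)"


def _matched_characteristics(cov: pd.DataFrame, sets_df: pd.DataFrame) -> pd.DataFrame:
    """Table of case/control counts and percentages in the matched sample."""
    merged = sets_df.join(cov.set_index("id"), on="subject_id")
    rows = []
    groups = {"cases": merged[merged["role"] == "case"],
              "controls": merged[merged["role"] == "control"],
              "total": merged}

    def add(label, fn):
        rows.append({"characteristic": label, **{g: fn(d) for g, d in groups.items()}})

    add("n", lambda d: str(len(d)))
    add(
        "median_followup_years_IQR",
        lambda d: "{:.1f} ({:.1f}-{:.1f})".format(
            *np.percentile(d["followup_years"], [50, 25, 75])
        ),
    )
    add(
        "median_age_years_IQR",
        lambda d: "{:.0f} ({:.0f}-{:.0f})".format(
            *np.percentile(d["age_at_baseline"], [50, 25, 75])
        ),
    )
    for sex in ("male", "female"):
        add(f"sex_{sex}", lambda d, s=sex: _pct((d["sex"] == s).sum(), len(d)))
    for morph in ("non_advanced", "advanced"):
        add(f"morphology_{morph}", lambda d, m=morph: _pct((d["morphology"] == m).sum(), len(d)))
    labels = {
        "high_cae": ("CAE<2", "CAE>=2"),
        "high_cna": ("CNA<3", "CNA>=3"),
        "high_loss": ("Loss<3", "Loss>=3"),
        "high_gain": ("Gain<3", "Gain>=3"),
    }
    for flag, (lo, hi) in labels.items():
        add(lo, lambda d, f=flag: _pct((~d[f].astype(bool)).sum(), len(d)))
        add(hi, lambda d, f=flag: _pct(d[f].astype(bool).sum(), len(d)))
    return pd.DataFrame(rows)


def _subjects_from_frame(cohort_df: pd.DataFrame):
    """Minimal Subject records (empty truth) from a cohort table, for matching."""
    from .cohort import Subject
    from .copynumber import ArmEventSet

    return [
        Subject(
            id=str(r["id"]),
            sex=r["sex"],
            age_at_baseline=float(r["age_at_baseline"]),
            morphology=r["morphology"],
            true_arm_events=ArmEventSet(sample_id=str(r["id"]), status={}),
            followup_years=float(r["followup_years"]),
            event=bool(r["event"]),
            event_time_years=float(r["event_time_years"]),
        )
        for _, r in cohort_df.iterrows()
    ]


def run_study(config: StudyConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "stages": {},
        "complete": False,
    }
    arm_map = ArmMap.hg38()
    stage = "init"
    try:
        # --- cohort -------------------------------------------------------
        stage = "cohort"
        t0 = time.perf_counter()
        if config.cohort_file:
            cohort_df = read_cohort(config.cohort_file)
            subjects = None
        else:
            params = CohortParams(**{**config.cohort, "seed": _stage_seed(config.seed, 0)})
            subjects = generate_cohort(params, arm_map)
            cohort_df = cohort_to_frame(subjects)
        cohort_df.to_csv(out / "cohort.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"][stage] = {"n_subjects": len(cohort_df),
                                     "seconds": round(time.perf_counter() - t0, 3)}

        # --- classification ----------------------------------------------
        stage = "classification"
        t0 = time.perf_counter()
        if subjects is not None:
            profiles = generate_profiles(
                subjects,
                bin_width=config.bin_width,
                noise_sd=config.noise_sd,
                seed=_stage_seed(config.seed, 1),
                arm_map=arm_map,
            )
            events, calls = [], []
            for prof in profiles:
                called = call_bins(prof, config.gain_threshold, config.loss_threshold)
                ev = derive_arm_events(called, arm_map, config.min_fraction)
                events.append(ev)
                calls.append(classify_molecular(ev))
            class_df = events_to_frame(events, calls)
            class_df.to_csv(out / "classification.tsv", sep="\t", index=False)
            # measured flags drive all downstream analyses
            cov = cohort_df.drop(columns=[c for c in _FLAGS + ["cae_count", "n_gains", "n_losses", "n_cna"] if c in cohort_df.columns])
            cov = cov.merge(
                class_df[["sample_id", "cae_count", "n_gains", "n_losses", "n_cna"] + _FLAGS],
                left_on="id",
                right_on="sample_id",
            ).drop(columns="sample_id")
        else:
            cov = cohort_df.copy()
            missing = [f for f in _FLAGS if f not in cov.columns]
            if missing:
                raise ConfigError(f"cohort file lacks molecular flags {missing}")
            cov.to_csv(out / "classification.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_samples": len(cov),
                                     "seconds": round(time.perf_counter() - t0, 3)}

        # --- crosstab (morphology × molecular) ----------------------------
        stage = "crosstab"
        xt = crosstab_morphology_molecular(cov, flag="high_cae")
        xt.to_csv(out / "crosstab_morphology_molecular.tsv", sep="\t")
        manifest["stages"][stage] = {"total": int(xt.attrs["counts"].loc["total", "total"])}

        # --- matching -----------------------------------------------------
        stage = "matching"
        t0 = time.perf_counter()
        if subjects is None:
            subjects = _subjects_from_frame(cohort_df)
        sets, report = match_cases(
            subjects,
            M=config.M,
            age_window=config.age_window,
            seed=_stage_seed(config.seed, 2),
            reuse_policy=config.reuse_policy,
            shortfall_policy=config.shortfall_policy,
            allow_future_cases=config.allow_future_cases,
        )
        audit_sets(sets, subjects, config.age_window, config.allow_future_cases)
        sets_df = sets_to_frame(sets)
        sets_df.to_csv(out / "matched_sets.tsv", sep="\t", index=False, float_format="%.6g")
        with open(out / "match_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        _matched_characteristics(cov, sets_df).to_csv(
            out / "matched_characteristics.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {"n_sets": len(sets), "n_dropped": report["n_dropped"],
                                     "seconds": round(time.perf_counter() - t0, 3)}

        # --- conditional-logistic models ----------------------------------
        stage = "models"
        t0 = time.perf_counter()
        uni_rows = []
        for name in config.univariate:
            fit = fit_matched(sets_df, cov, [_term_for(name)])
            uni_rows += _fit_row(f"univariate:{name}", fit)
        pd.DataFrame(uni_rows).to_csv(out / "univariate_fits.tsv", sep="\t", index=False,
                                      float_format="%.6g")
        multi_rows = []
        for spec in config.multivariate:
            terms = [_term_for(n) for n in spec]
            fit = fit_matched(sets_df, cov, terms)
            X, y, groups, _ = matched_arrays(sets_df, cov, terms)
            cstat = matched_concordance(X @ fit.beta, y, groups)
            model_name = "multivariate:" + "+".join(spec)
            rows = _fit_row(model_name, fit)
            for r in rows:
                r["harrell_c"] = cstat
            multi_rows += rows
        pd.DataFrame(multi_rows).to_csv(out / "multivariate_fits.tsv", sep="\t", index=False,
                                        float_format="%.6g")

        # subgroup contrasts: combined morphology × molecular categorical,
        # refitted once per reference cell
        sub_rows = []
        for ref in [("non_advanced", False), ("advanced", False), ("non_advanced", True)]:
            term = Term(
                name="morph_mol",
                kind="categorical",
                columns=("morphology", config.subgroup_flag),
                reference=ref,
            )
            model_name = f"subgroup:ref={ref[0]}&{config.subgroup_flag}={ref[1]}"
            try:
                fit = fit_matched(sets_df, cov, [term])
            except ConvergenceError as exc:
                # sparse joint cells can separate; flag rather than abort
                sub_rows.append({"model": model_name, "covariate": "", "OR": np.nan,
                                 "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                                 "coef": np.nan, "se": np.nan, "n_sets": len(sets),
                                 "converged": False, "note": str(exc)})
                continue
            sub_rows += _fit_row(model_name, fit)
        pd.DataFrame(sub_rows).to_csv(out / "subgroup_contrasts.tsv", sep="\t", index=False,
                                      float_format="%.6g")
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        # --- time-stratified fits -----------------------------------------
        stage = "windows"
        t0 = time.perf_counter()
        win_rows = []
        for name in config.window_exposures:
            fits = stratified_window_or(
                sets_df, cov, [_term_for(name)], windows=[tuple(w) for w in config.windows]
            )
            for win, fit in fits.items():
                n_sets_w = int(
                    ((sets_df["index_time_years"] > win[0])
                     & (sets_df["index_time_years"] <= win[1])
                     & (sets_df["role"] == "case")).sum()
                )
                if fit is None:
                    win_rows.append({"window": window_label(win), "exposure": name,
                                     "n_sets": n_sets_w, "OR": "", "ci_low": "", "ci_high": "",
                                     "p": "", "note": "not estimable"})
                else:
                    s = fit.summary().iloc[0]
                    win_rows.append({"window": window_label(win), "exposure": name,
                                     "n_sets": fit.n_sets, "OR": f"{s['OR']:.6g}",
                                     "ci_low": f"{s['ci_low']:.6g}",
                                     "ci_high": f"{s['ci_high']:.6g}",
                                     "p": f"{s['p']:.6g}", "note": ""})
        pd.DataFrame(win_rows).to_csv(out / "windowed_fits.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        # --- survival ------------------------------------------------------
        stage = "survival"
        t0 = time.perf_counter()
        km_rows = []
        logrank_out = {}
        for group_col in ("morphology", "high_cae"):
            curves = km_by_group(cov, group_col, max_years=config.km_truncate_years)
            for level, km in curves.items():
                df = km.to_frame()
                df.insert(0, "group", f"{group_col}={level}")
                km_rows.append(df)
            chi2, p, df_ = logrank_test(
                cov[group_col].values, cov["event_time_years"].values, cov["event"].values
            )
            logrank_out[group_col] = {"chi2": chi2, "p": p, "df": df_}
        pd.concat(km_rows, ignore_index=True).to_csv(
            out / "km_curves.tsv", sep="\t", index=False, float_format="%.10g"
        )
        with open(out / "logrank.json", "w") as fh:
            json.dump(logrank_out, fh, indent=2, sort_keys=True)
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        manifest["complete"] = True
    except CaeriskError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        exc.args = (f"stage {stage!r}: {exc}",)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
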