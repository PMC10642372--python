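# caerisk

Colorectal adenomas are removed at colonoscopy, and surveillance intensity is
decided from their morphology: an *advanced adenoma* (AA; ≥10 mm, high-grade
dysplasia, or ≥25% villous component) marks the patient as high risk for a
later, *metachronous* colorectal cancer (me-CRC). Chromosomal instability
offers a molecular alternative: seven direction-specific chromosome-arm
copy-number alterations — gains of 8q, 13q and 20q, losses of 8p, 15q, 17p and
18q, the **cancer-associated events (CAEs)** — accumulate as adenomas progress
toward carcinoma, and an adenoma carrying **≥2 CAEs** can be classified as
*molecular high-risk* (alternative burden definitions: ≥3 altered arms, ≥3
gains, ≥3 losses).

`caerisk` implements the full epidemiological machinery needed to ask whether
such a molecular classification of the *baseline* adenoma predicts me-CRC in a
surveillance cohort, as a reusable, tested Python library:

* **Synthetic cohorts** (`caerisk.cohort`) — subjects with sex, age, adenoma
  morphology, true arm events consistent with requested prevalences, and
  exponential time-to-event outcomes with covariate log-hazard effects, plus
  bin-level log2-ratio profiles generated from the truth. Everything is
  seeded, so every downstream stage is testable without patient data.
* **Copy-number classification** (`caerisk.copynumber`, `caerisk.arms`) —
  threshold calling of binned log2 ratios, arm-level event derivation
  (≥50% of an arm's bins altered in one direction), CAE and burden counting,
  the four high-risk flags, and the morphology × molecular crosstab.
* **Incidence-density matching** (`caerisk.matching`) — each case matched to
  M controls (default 2) of the same sex, baseline age within ±5 years, whose
  follow-up is at least the case's event time (risk-set sampling), with
  explicit reuse and shortfall policies and a re-audit routine.
* **Conditional logistic regression** (`caerisk.clogit`) — the matched-set
  conditional likelihood implemented from first principles:

  ```
  ℓ(β) = Σ_s [ x_case(s)·β − log Σ_{j∈s} exp(x_j·β) ]
  ```

  with exact gradient/Hessian, Newton–Raphson with step halving, Wald 95% CIs
  (OR = e^β), a 1-df score test that reduces to the Cochran–Mantel–Haenszel
  statistic for binary exposures, separation detection, interaction and
  combined-categorical design terms, and a within-set Harrell's concordance.
* **Survival analysis** (`caerisk.survival`) — Kaplan–Meier product-limit
  estimation, the k-group log-rank test, and time-window-stratified
  conditional-logistic fits (≤1, 1–2, 2–3, >3 years).
* **Design arithmetic** (`caerisk.power`) — weighted null prevalences,
  shifting a prevalence pair to a target odds ratio under a mean-preserving
  constraint, pooled-variance analytic power for the 1:M matched design, and
  a score-test power simulation.
* **Pipeline & CLI** (`caerisk.pipeline`, `caerisk`) — one declarative YAML
  config driving generate → classify → match → fit → report, with a manifest
  and byte-reproducible outputs.

## Worked example

```python
from caerisk import analytic_power, CohortParams, generate_cohort, match_cases
from caerisk.cohort import cohort_to_frame
from caerisk.clogit import Term, fit_matched
from caerisk.matching import sets_to_frame

# power of the matched design: 32% vs 13% exposure, 69 cases / 137 controls
print(round(100 * analytic_power(0.32, 0.13, 69, 137, alpha=0.05), 1))  # 90.3

cohort = generate_cohort(CohortParams(n_subjects=521, seed=7))
sets, report = match_cases(cohort, M=2, seed=11)
fit = fit_matched(
    sets_to_frame(sets),
    cohort_to_frame(cohort),
    [Term(name="advanced", kind="indicator", column="morphology", level="advanced")],
)
print(fit.summary().round(3))
```

`90.3` is the percent power of the two-proportion pooled-variance test at
two-sided α = 0.05 — the design supports detecting a 3-fold odds ratio. The
fit summary prints the within-set odds ratio for advanced morphology with its
Wald Cl: with this seed, `OR 6.46 (3.52–11.84)`. The generator plants a
hazard ratio of 2.9 on AA status; the matched estimate sits above it for two
documented reasons — sampling noise is large at ~115 matched sets, and with a
common outcome (~22% of subjects become cases) drawing controls only from
subjects who never develop the outcome inflates the odds ratio relative to
the hazard ratio. Rerunning the matching with `allow_future_cases=True`
(textbook risk-set sampling) on a 6000-subject cohort returns
`OR 3.06 (2.65–3.53)`, straddling the planted effect; see `docs/methods.md`.

The same workflow from the shell:

```bash
cat > study.yaml <<EOF
seed: 7
cohort: {n_subjects: 521}
outdir: study_out
EOF
caerisk run-all --config study.yaml
```

writes `cohort.tsv`, `classification.tsv`, the morphology × molecular
crosstab, `matched_sets.tsv` + `match_report.json`, the matched-sample
characteristics table, univariate/multivariate/subgroup/windowed conditional
logistic fits, `km_curves.tsv`, `logrank.json` and a `manifest.json`. A run
with seed 7 yields, for example, the crosstab

```
molecular_risk  advanced        non_advanced    total
high            81 (31.6)       20 (7.5)        101 (19.4)
low             175 (68.4)      245 (92.5)      420 (80.6)
total           256 (100.0)     265 (100.0)     521 (100.0)
```

(column percentages; compare the generator's targets of 31.8% high-risk
within AA and 10.3% within non-AA) and a univariate fit table whose
`advanced` row reads `OR 3.12 (1.88–5.17), p = 1.1e-05`.

`caerisk design` prints the design report: weighted null prevalences
(13.56% cohort, 16.64% cases, 13.12% controls), the OR-3 shifted pair
(21.4%, 8.3%), and analytic power under both variance conventions.

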