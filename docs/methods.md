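# Methods

This note documents the statistical models implemented in `caerisk`, the
assumptions behind the synthetic-data generator, the numerical choices that
were genuinely open, and the limits of what the test suite demonstrates.

## The scientific setting

Subjects enter a surveillance cohort when a single colorectal adenoma is
removed at baseline colonoscopy (age ≥ 40). The adenoma is classified two
ways: morphologically, as advanced (AA) versus non-advanced; and molecularly,
from its DNA copy-number profile. Binned log2 ratios are called per bin,
aggregated to chromosome-arm events, and scored for the seven
cancer-associated events (CAEs): gains of 8q, 13q, 20q and losses of 8p, 15q,
17p, 18q. An adenoma with ≥2 CAEs is molecular high-risk; alternative burden
definitions flag ≥3 altered arms, ≥3 gains, or ≥3 losses. The outcome is
metachronous colorectal cancer (me-CRC) during follow-up. The association
between baseline classification and outcome is estimated by a nested
case-control design: 2:1 incidence-density matching on sex and age (±5
years), controls restricted to the case's risk set, and conditional logistic
regression on the matched sets.

## Synthetic cohort model

`generate_cohort` draws, per subject:

* sex ~ Bernoulli(0.44 male), age ~ Normal(69, 10²) truncated at 40 —
  matching a typical surveillance cohort's median age of about 69;
* morphology ~ Bernoulli(p_advanced = 0.505);
* molecular truth: with probability 0.318 (AA) / 0.103 (non-AA) the subject
  is CAE-high and receives 2–4 CAEs (weights 0.55/0.30/0.15 — most high-risk
  adenomas sit just over the threshold); otherwise 0 or 1 CAE (one with
  probability 0.25). Each non-CAE eligible arm is independently altered with
  probability 0.03 (direction 50/50), giving realistic variation in the
  burden flags without tying them deterministically to CAE status;
* event time T ~ Exponential(λ), log λ = log λ₀ + Σ β_k x_k with
  λ₀ = 0.01/year and default effects β_advanced = log 2.9,
  β_high_loss = log 2.3 — the effect sizes the matched analysis is meant to
  recover;
* administrative censoring C ~ Uniform(3, 23) years. A single censoring
  horizon cannot produce both a ~13-year median and a wide IQR, so entry is
  staggered: the uniform window gives median follow-up ≈ 13 years with
  IQR ≈ 8–18 among event-free subjects, close to the ~13.0 (7.3–17.0)
  follow-up structure of long national surveillance cohorts. Subjects with
  T ≤ C are cases with event_time = followup = T; otherwise followup = C.

With these defaults roughly 20–25% of subjects develop the outcome — the
case-enriched regime a nested case-control analysis is designed for.

**OR ≈ HR caveat.** The generator plants *hazard* ratios; conditional
logistic regression on matched sets estimates *odds* ratios. Under risk-set
sampling in which later cases may serve as earlier cases' controls
(`allow_future_cases=True`), the matched odds ratio consistently estimates
the hazard ratio regardless of outcome frequency. The default policy,
however, follows the study design being emulated: controls are drawn only
from subjects who *never* develop the outcome. With a common outcome this
survivor-only policy inflates the estimate (empirically ≈ 3.5 for a planted
2.9 at 6000 subjects). Both policies are selectable; parameter-recovery
claims in the test suite are therefore made on directly simulated matched
sets with independent Bernoulli exposures, where the planted odds ratio is
the estimand by construction.

`generate_profiles` tiles every arm of the arm map with fixed-width bins
(default 100 kb, 0-based half-open; the last bin of an arm is truncated) and
emits log2 ratio = segment mean + Gaussian noise: +0.58 (log2 3/2) for gains,
−1.0 (log2 1/2) for losses, 0 for neutral, noise sd 0.05. Magnitudes are
configurable; they correspond to clonal single-copy changes in a diploid
background without FFPE artifacts, GC/mappability bias, read-count noise or
subclonality — so a passing round-trip shows the *pipeline logic* is exact,
not that the caller would be error-free on degraded archival material.

## Arm map and classification

Arms are read from a UCSC cytoBand-dialect file and collapsed to one
interval per arm. The packaged map is a deliberately coarse, synthetic
one-band-per-arm hg38 table (autosomes only; approximate centromere
boundaries); it is sufficient because simulation and classification share
the same map, and a full cytoBand file can be substituted for real data.
Acrocentric short arms (13p, 14p, 15p, 21p, 22p) and the sex chromosomes are
excluded from the eligible arms, leaving 39.

Per-bin calling is a fixed threshold rule (gain if log2 ratio ≥ 0.10, loss
if ≤ −0.10): deterministic and adequate at the simulated noise level, in
place of a mixture-model caller. At noise sd 0.05 the thresholds sit exactly
2 sds from a neutral bin's mean, so ~4.6% of neutral bins miscall
individually — harmless at arm level, where an event requires ≥ min_fraction
(default 0.5) of the arm's covered bins altered in one direction. When both
directions pass the fraction threshold the larger fraction wins and an exact
tie is neutral; arms with no covered bins are neutral. Burden counts
(n_gains, n_losses, n_cna) are at arm resolution, and a whole-chromosome
event counts as two arm events. Report percentages are formatted to one
decimal, rounding half away from zero.

## Matching

Cases are processed in ascending event-time order (ties by id): earlier
cases face the largest risk sets, which maximizes feasibility under
sampling without replacement, and the order is deterministic. Eligibility is
exact-sex, closed age window (|Δage| ≤ 5.0 as stored, no rounding),
follow-up ≥ the case's event time, and — by default — no history of the
outcome at any time. Controls are drawn uniformly at random (seeded) from
the sorted eligible list. Under `without_replacement` (default) a control
serves in at most one set; cases with fewer than M eligible controls are
dropped and reported (`shortfall_policy="keep"` retains smaller sets).
`audit_sets` re-verifies every emitted set against the same rules.

## Conditional logistic regression

The conditional likelihood for a set s with case c(s) is
P(case = c(s) | one case in s) = exp(x_c·β) / Σ_{j∈s} exp(x_j·β). The
log-likelihood, gradient Σ_s (x_c − E_w[x]) and Hessian −Σ_s Cov_w(x) (w the
within-set softmax weights) are computed exactly with per-set max
subtraction for numerical stability. Newton–Raphson starts at β = 0 with up
to 20 step-halvings per iteration; convergence is max |gradient| < 1e-8
within 50 iterations. Sets without within-set covariate variation carry no
information and are counted in diagnostics; a covariate constant within
every set is rejected.

*Separation.* When the MLE is infinite the gradient decays monotonically to
zero along the diverging coefficient, so no gradient-based rule can
distinguish separation from slow convergence; the fit therefore declares
separation whenever ‖β‖∞ exceeds 10 (odds ratio > e^10 ≈ 2.2·10⁴) before
the gradient criterion is met, naming the offending covariate.

Inference is Wald: OR = e^β, 95% CI = exp(β ± 1.96·se), p from z = β/se —
matching how matched case-control studies conventionally report; profile
likelihood CIs are out of scope. Age enters in years, untransformed. The
1-df score test uses U(0)²/I(0) and equals the Cochran–Mantel–Haenszel
statistic (no continuity correction) for binary exposures. Subgroup
contrasts of the morphology × molecular cross-classification are fitted as
one 4-level combined categorical with a selectable reference cell rather
than refitting per pair. Harrell's concordance is computed over within-set
(case, control) pairs — the pairing the matched design actually constrains —
with ties counted 0.5.

## Survival and time stratification

The Kaplan–Meier estimator and k-group log-rank test are standard
implementations (events before censorings at tied times; hypergeometric
variance/covariance accumulated over pooled event times, statistic on k−1
groups). Curves are computed on cohort subgroups defined by baseline
classification with time from baseline colonoscopy; an optional truncation
(e.g. 5 years) censors later follow-up for short-horizon comparisons.
Time-stratified odds ratios assign each matched set to the half-open window
(lo, hi] containing the case's event time (defaults (0,1], (1,2], (2,3],
(3,∞)) and refit per window; windows with no informative sets or with
non-estimable (separated) fits are flagged rather than fitted — expected
behaviour in sparse early windows.

## Design arithmetic

The expected prevalence of molecular high-risk features in a group that is
a morphology mixture is the weighted sum w_AA·p_AA + w_nAA·p_nAA (defaults
p = 25%/3%; weights 48/52 cohort, 62/38 cases, 46/54 controls, giving
13.56%, 16.64%, 13.12%). `shift_to_target_or` moves a null pair (p_case,
p_ctrl) apart until their odds ratio hits a target while preserving the
arithmetic mean (default) or the 1:M size-weighted mean, by Brent
root-finding on the control prevalence to 1e-10; shifting (16.7%, 13.1%) to
OR 3 gives (21.5%, 8.3%). Analytic power uses the two-proportion normal
approximation; the default evaluates both the critical value and the power
at the pooled-variance null SE, which yields 90.3% for 32% vs 13% with
69/137 at α = 0.05 — the convention consistent with a stated 90% design
power — while the unpooled-alternative variant gives 88.5%. Note the printed
design pair (32%, 13%) is not the mean-preserving shift of (16.7%, 13.1%)
under either constraint (that shift gives 21.5%/8.3%, power ≈ 76%), so the
power functions accept explicit proportions. `simulate_power` draws 1:M
sets with independent Bernoulli exposures and rejects via the conditional
score test; it agrees with the closed form within Monte-Carlo error. The
prevalence-estimation helper n = p(1−p)/SE² is reported (300 at 25%±2.5%,
186.24 at 3%±1.25%) but involves rounding conventions outside our control,
so it is informational.

## Pipeline determinism

All randomness flows from one root seed, split per stage with
`numpy.random.SeedSequence.spawn`; identical config + seed reproduce every
output file byte-for-byte (the manifest additionally records wall-clock
stage timings and a config hash). Genomic coordinates are 0-based half-open
throughout; tables are TSV with `%.6g` floats.

## Problem sizes and what the tests show

Unit and property tests run at deliberately modest sizes chosen for tight
feedback: cohorts of 150–2 500 subjects for distributional checks (with the
prevalence-convergence test at 20 000 and a 4·standard-error tolerance),
1 Mb bins for profile round-trips (bin width only changes the number of
bins per arm, not the arm-level decision at these noise levels), 2 000
matched sets × 200 replicates for estimator recovery and CI coverage, and
1 000 replicates for test-size checks. Passing these demonstrates internal
correctness of the estimators and the pipeline under the generator's
idealized assumptions — clonal events, Gaussian bin noise, exponential
hazards, independent subjects — not performance on FFPE-derived,
subclonal, or registry-linked real data.

## Known limitations

* Exponential event times (constant baseline hazard); no competing risks,
  no Cox regression.
* One adenoma per subject; no multi-lesion or repeat-colonoscopy structure.
* The threshold caller ignores segment-level correlation; it is not a
  substitute for mixture-model calling of real low-coverage data.
* Survivor-only control sampling (the default, mirroring the emulated
  design) does not consistently estimate the hazard ratio when the outcome
  is common; see the OR ≈ HR caveat above.
* Wald inference only; small-sample exact conditional inference and
  Firth-type corrections are out of scope.
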