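# Methods

`gpcontinuity` implements a complete desk-scale analysis of relational
continuity of care in general practice: patient-level continuity
indices computed from consultation records, cohort construction under
explicit eligibility rules, and multilevel regression of continuity on
patient covariates with practice-level clustering. Because real
primary-care record extracts cannot be redistributed, the package pairs
the analysis code with a synthetic record generator whose
provider-concentration structure has known analytic truth; every claim
the test-suite makes is therefore checked against either exact
arithmetic, an exhaustive brute-force oracle, a closed form, or a
Monte-Carlo oracle with stated error.

## Continuity indices

Both indices are functions of the *visit profile*: the vector
n = (n_1, …, n_k) of a patient's visit counts per GP within an analysis
window, with N = Σ n_i total visits.

**Usual Provider of Care (UPC)** — the share of visits made to the most
frequently seen GP:

    UPC = max_i n_i / N,   UPC ∈ (0, 1].

**Bice–Boxerman Continuity of Care (COC)** — the concentration of
visits across all GPs seen:

    COC = (Σ_i n_i² − N) / (N (N − 1)),   COC ∈ [0, 1].

COC is exactly the proportion of ordered visit pairs made to the same
GP (pairwise concordance); the test-suite verifies this equivalence
exhaustively for every visit composition with 2 ≤ N ≤ 8 over up to four
providers, along with the invariants COC ≤ UPC, permutation invariance,
merge monotonicity, and scale behaviour. COC is undefined for N < 2
(the denominator vanishes) and is returned as NaN rather than raising,
so bulk computation proceeds; cohort rules (minimum three consultations)
make this unreachable in the standard analysis.

A note on the verbal definition of COC in circulation: stated as "the
squared per-GP counts summed and divided by N(N−1)", it omits the −N in
the numerator; the canonical two-scenario example (COC 0.22 for
5+1+1+1+1+1 and 0.44 for 5+5) is only consistent with the subtraction,
and the standard form above is implemented.

Indices are stored at full floating precision; rounding to two decimal
places happens only in rendered reports.

## Synthetic record generator

The generator emulates the nesting structure of UK primary-care data:
practices, several GPs per practice (default 8), patients registered to
one practice with covariates (7 age bands from 18–29 to ≥80, sex,
an 11-category ethnicity mix, deprivation quintiles Q1–Q5 with Q1 least
deprived), long-term conditions flagged physical or mental with onset
before baseline, and per-patient consultation streams over a 4-year
window (2016-01-01 to 2019-12-31 inclusive; 1461 days = 4.00 years of
365.25 days).

For patient *i* in a practice with G GPs:

* **Concentration.** log α_i = β₀ + β_eth + β_dep·(q_i − 1) + β_age +
  β_sex + u_practice, with u_practice ~ N(0, σ²_practice). Provider
  preference weights p_i ~ Dirichlet(α_i, …, α_i). Small α_i means
  concentrated weights (high continuity); large α_i approaches uniform
  allocation.
* **Volume.** Total visits N_i ~ negative binomial with mean
  μ_i = μ₀ · (at-risk fraction of window) · exp(age shift + 0.08·LTC
  count) and dispersion k (variance μ + μ²/k). Defaults: μ₀ = 12 visits
  per 4 years, k = 1.4 (strong overdispersion, as in real consultation
  counts). Consultation volume thus confounds continuity, which is why
  every regression adjusts for it.
* **Allocation.** Each visit's GP is drawn iid from p_i; dates are
  uniform over the patient's at-risk interval; modes are categorical
  (face-to-face 72%, telephone 23%, online 3%, home visit 2% — the last
  excluded by the default mode filter downstream). 10% of patients
  receive an exit date uniform over the window, truncating both their
  at-risk interval and their follow-up time.

This Dirichlet-multinomial design was chosen because it provides one
concentration dial with analytic anchors at both ends and in between:

* α → 0: all weight on one GP, UPC = COC = 1;
* α → ∞: uniform multinomial allocation, for which
  E[Σ n_i²] = N + N(N−1)/G gives **E[COC] = 1/G exactly**;
* any α: E[COC | p, N] = Σ p_i², and averaging over the symmetric
  Dirichlet gives **E[COC] = (α + 1)/(Gα + 1)** for every N ≥ 2.

The defaults put the baseline at α = 0.75 with G = 8, so baseline
E[COC] = 0.25 — the order of magnitude observed in English general
practice — and mean UPC ≈ 0.45. Covariate offsets on log α (positive =
more diffuse care) are oriented to reproduce the qualitative ordering
reported for English practices: lower continuity for Bangladeshi,
Pakistani and Black ethnic groups, slightly higher for Indian and
Chinese groups, lower continuity with deprivation (+0.05 per quintile
step), higher continuity at older ages. These offsets control ordering
and rough size only; no attempt is made to match published marginal
percentages beyond orders of magnitude.

Mean **UPC** has no convenient closed form, so the package ships a
simulation oracle (`simulate_mean_upc`) and a calibration routine
(`calibrate_offset_for_upc_gap`) that bisects on the log-α offset, with
common random numbers across evaluations, until a requested mean-UPC
gap (e.g. −0.03) is achieved. The parameter-recovery test generates
data at the calibrated offset and requires the fitted group coefficient
to land within 3 standard errors of the target.

All randomness descends from a single root seed through named
`SeedSequence` child streams (population 0, consultations 1, practice
intercepts 2); identical configuration and seed reproduce every table
byte for byte.

**What the generator does not emulate.** Visits are exchangeable within
a patient: there is no episode clustering, no seasonality, no GP
turnover or registration churn, and no within-window drift of
preferences. One measurable consequence: because
E[COC | p] = Σ p_i² at every N, mean COC is *window-length invariant*
under this design, whereas in real records shorter windows show higher
COC as well as higher UPC. The package's direction checks therefore
assert the UPC window effect strictly (it is a small-sample property of
the max-share statistic, present in any design) and assert that COC
agrees between windows within Monte-Carlo noise, which is the
generator's true implication. Passing tests show the pipeline recovers
known generative truths; they do not certify behaviour under temporal
dynamics the generator omits.

## Cohort construction

Eligibility is applied in a fixed order, each patient tallied under the
first rule that excludes them (registration at baseline → minimum age →
optional data-quality flag → minimum consultation count → missing
covariates), so the exclusion tallies plus survivors always sum to the
input count and can be rendered as a flow chart. Defaults: baseline
2016-01-01, window end 2019-12-31 (inclusive), age ≥ 18, at least three
consultations with a GP in person, by telephone or online. All window
membership uses half-open intervals [start, end + 1 day).

Follow-up is (min(exit, practice closure, window end + 1 day) −
baseline) in 365.25-day years. Continuity indices are computed over the
fixed calendar window intersected with each patient's registration
period, consistent with adjusting for follow-up length in the models.

**Ethnicity** arrives as dated observations from two sources. The
primary-care record takes precedence whenever it has any observation;
hospital-admission coding is a fallback only. Within a source the modal
category wins, ties break to the most recent observation, remaining
ties to a fixed category order. This rule is the package's own
deterministic choice (published multi-observation algorithms for EHR
ethnicity are not specified in enough detail to reimplement); any
deterministic rule yields a valid pipeline, and the rule used is
documented and tested. The main 11-category scheme collapses White
British, Irish and Other White to "White"; the disaggregated scheme
keeps 16 detailed categories for sensitivity analysis.

**Long-term conditions** are counted as distinct labels with onset on
or before baseline. The four-way category applies the precedence: 0–1
conditions; otherwise "physical+mental" whenever at least one of each
class is present (this subsumes patients with ≥2 of both); otherwise
"2+ physical" or "2+ mental". Categories are mutually exclusive and
exhaustive, verified against a brute-force re-derivation over all 2⁴
presence archetypes. Conditions are counted if ever onset on or before
baseline; resolution is not modelled.

Same-day repeat contacts count separately only when their recorded
timestamps differ; identical (patient, GP, timestamp, mode) duplicates
collapse to one event upstream of this package's tables.

## Regression models

The outcome (UPC or COC) is modelled untransformed on [0, 1] with a
linear mixed model: fixed effects for covariates, a practice-level
random intercept for clustering, patient-level residual. Fitting is
restricted maximum likelihood (REML) — standard for variance
components; a flag switches to ML. Every model includes follow-up years
and consultation count as continuous, uncentred nuisance terms.
Reference levels: age 18–29, male, Q1 (least deprived), White (White
British in the disaggregated scheme), condition category "0–1".

The sequence: model 1 fits each covariate separately (with the nuisance
terms — the "bivariate" description elsewhere notwithstanding, the
nuisance terms are always in); model 2 adds age, sex, deprivation,
condition count and ethnicity jointly; model 3 replaces the count with
the four-way category; model 4 refits the model-2 design without
condition terms on the ≥2-condition subgroup. The 12-month sensitivity
suite is the model-2 design on a cohort built with a 2016-only window.

95% CIs are Wald intervals (estimate ± 1.96·SE); significance marking
is two-sided p < 0.05 with no multiple-testing correction, matching the
presentation convention of descriptive inequality analyses. Missing
covariate rows are dropped (complete case) with the count recorded on
the result. Non-convergence is flagged, not raised. A single practice
cannot identify the random intercept and raises a degenerate-design
error advising OLS; the τ² = 0 limit of the mixed model is available as
`ols_fixed_effects` (evaluated inside the mixed-model GLS machinery at
a variance twelve orders below the outcome scale, since the exactly-zero
covariance takes a singular fallback path in the optimizer) and is
verified to match ordinary least squares to ≤ 10⁻⁶ relative.

Known limitations of the modelling layer: the linear model ignores the
boundedness of the indices (predictions can leave [0, 1] for extreme
covariates); variance components at the boundary (true τ² = 0) are
estimated near but not exactly zero; no random slopes or
cross-classification (patients do not move practices in this design).

## Problem sizes and numerical tolerances

The test-suite's stochastic checks use sizes chosen to make their
Monte-Carlo tolerances meaningful at interactive runtimes: 2 000
patients per point for closed-form and monotonicity grids (mean COC
within 3 SEs of 1/G; monotone within 2 SEs per step), 5 000 patients ×
20 seeds for null CI coverage (≥ 18/20 nominal-95% coverage), 10 000
patients for calibrated-gap recovery (within 3 SEs of −0.03), boundary
variance recovery (practice variance ≤ 1% of residual variance) and
additivity (coefficient shifts < 2 SEs under joint adjustment).
Exhaustive oracle checks are exact, with no tolerance. Bisection for
calibration stops at 10⁻³ on the offset; Dirichlet weights degenerate
at α below ~10⁻³⁰⁰ are replaced by the exact one-hot limit.
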