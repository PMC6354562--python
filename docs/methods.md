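# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions and the deliberate design choices in `anclives`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## 1. The cascade model of effective coverage

An intervention-coverage indicator for a lives-saved projection should measure
*effective* coverage: the proportion of women who truly needed an intervention
and were correctly managed, among those attending care. Record-level data allow
this to be built as a cascade

```
eligible (attending care)
  ⊇ screened correctly and at the correct time
    ⊇ screen-positive
      ⊇ correctly managed
```

with the composite indicator the product of the two stage proportions:
`(screened/eligible) × (managed/positive)`. Algebraically this equals correctly
managed true positives divided by the estimated number of true positives among
all attenders (extrapolating the positivity rate of the screened to the
unscreened), which is the quantity of interest. Both stage proportions are
reported alongside the composite (`CascadeResult.screening_stage`,
`.management_stage`), since the management stage alone — managed over observed
positives — is the other defensible composite denominator and users may prefer
it; the product form is primary.

Screening rules per indicator:

* **Diabetes** — urine sugar at the booking (first) visit; if not already
  positive, a blood-sugar test inside the 24–28-week window (closed on both
  ends; a test outside the window does not count); a glucose challenge test
  when the preceding step is positive. Positive: challenge > 140 mg/dl.
  Correct management: referral (high-risk clinic or hospital) at or after the
  challenge.
* **Hypertensive disorders** — blood pressure at *every* attended visit
  (serial screening; one missing measurement fails the stage). Positive: any
  measurement ≥ 140 mmHg systolic or ≥ 90 diastolic. Management: urine
  protein testing for mild gestational hypertension (first elevation at
  > 20 weeks, never in the severe range), any referral for chronic disease
  (first elevation before 20 weeks), hospital referral for moderate/severe
  disease (any measurement ≥ 160/110).
* **Pre-eclampsia** — a urine protein test at every visit where hypertension
  is measured after 20 weeks. Positive: such a visit with positive
  proteinuria. Management: hospital referral at or after the first positive
  visit. An optional symptoms flag (`ClinicalThresholds.symptoms_qualify`,
  default off) lets symptomatic women without proteinuria count as positive;
  the default keeps the strictly test-based definition.
* **Tetanus** — paper dialect: immune at entry or any documented dose;
  eRegistry dialect: entry status documented *and* (immune, or dosed when
  unknown/unimmunized).
* **Iron-folate** — paper dialect: the single checkbox (any supplement
  given); eRegistry dialect: correct type given observed anemia status
  (treatment dose for anemic women, routine dose otherwise), pooled.

Management correctness is judged at the clinic: a correct referral counts
regardless of follow-through at the receiving facility. No stratification by
socio-economic covariates is performed (screening and management are assumed
equitable).

### Conventions and edge cases

* Thresholds written as "below X or less" in guideline prose are internally
  contradictory; every cut here is **strict `<`** (anemia < 11 g/dl, severe
  < 7, BMI < 18.5) and configurable via `ClinicalThresholds`.
* **Missing data** are conservatively read as "care not demonstrated": a
  missing screening test fails the screening stage, a pregnancy with no
  tetanus documentation stays in the denominator as unvaccinated. Tetanus and
  the health-status indicators accept `missing_policy="complete_case"` to drop
  undocumented records instead.
* **Referral censoring.** Women referred to hospital do not return to the
  primary-care clinic; `apply_referral_censoring` drops all visits after the
  first hospital referral (the referral visit itself is kept — it carries the
  management event). Two eligibility consequences follow: a pregnancy censored
  before any attended visit reaches 24 weeks cannot complete diabetes
  screening and is excluded from that cascade's eligible pool, and one
  censored at or before 20 weeks is likewise excluded from the pre-eclampsia
  cascade. Without these exclusions the full-compliance limit could not reach
  1.0, which would misread censoring as a quality failure.
* Empty denominators (no screen-positives, or no eligible women) are flagged
  `undefined=True` with `coverage=0.0` — never a silent zero and never NaN.
* Blood-pressure cuts (140/90, severe 160/110) are conventional values, set in
  `ClinicalThresholds` because guideline prose names categories, not mmHg.

## 2. The synthetic cohort generator

The generator emulates a public-sector antenatal cohort of the kind the
cascades were designed for: one row per visit, booking between weeks 8 and 16
(uniform — no enrollment distribution is published), subsequent visits at the
scheduled weeks `12, 16, 20, 24, 26, 30, 34, 38` that fall after booking.
Latent conditions are drawn per pregnancy:

| parameter | default | rationale |
|---|---|---|
| `incidence_diabetes` | 0.08 | gestational-diabetes range for the region |
| `incidence_chronic_htn` | 0.01 | chronic hypertension in pregnancy |
| `incidence_gest_htn_mild` | 0.04 | mild gestational hypertension |
| `incidence_gest_htn_modsev` | 0.02 | moderate/severe gestational hypertension |
| `incidence_preeclampsia` | 0.03 | sampled *within* hypertensives (see below) |
| `anemia_hb_mean`, `anemia_hb_sd` | 11.4, 1.2 g/dl | puts anemia (< 11) near 37% |
| `severe_anemia_floor` | 0.001 | severe anemia is rare in this population |
| `low_bmi_prob` | 0.035 | low-BMI prevalence a few percent |
| `tetanus_immune_at_entry_prob` | 0.5 | half of women enter already immune |
| `screening_compliance` | 0.40 / 0.50 / 0.60 | diabetes / hypertension / pre-eclampsia |
| `management_compliance` | 0.25 / 0.70 / 0.13 / 0.85 | + tetanus |
| `iron_folate_given_prob` | 0.64 | supplementation in the low 60s |
| `missingness['tetanus']` | 0.07 | eRegistry-level documentation gaps |
| `missingness['tetanus_paper']` | 0.42 | paper-record documentation gaps |

Compliance defaults were chosen once so the composite indicators land in the
ranges registry data report for this setting (cascade indicators in the low
double digits, tetanus and iron-folate high), with the tetanus baseline left
below the 90% scale-up target so the scenario has headroom.

Mechanics worth knowing:

* Conditions surface **only through the screening pathway**: a diabetic woman
  produces a positive blood sugar and a glucose challenge above the cut only
  when the pathway was followed (per-pregnancy Bernoulli at the screening
  compliance); a hypertensive woman shows elevated pressure only at visits
  where it was measured. Urine sugar at booking is recorded but insensitive
  (always negative) — detection runs through the blood-sugar step — so the
  screen-positive fraction among the screened is a clean binomial at the
  configured incidence.
* Hypertensive categories are mutually exclusive; gestational onset is uniform
  over weeks 20–32. Pre-eclampsia is sampled among hypertensive pregnancies at
  conditional probability `inc_pe / (inc_chronic + inc_mild + inc_modsev)` so
  its marginal frequency matches the configured incidence; onset is uniform
  over weeks max(21, onset+1)–36. A moderate/severe case hospital-referred
  before pre-eclampsia onset is censored and never observed positive — a
  deliberate censoring feature, not a bug.
* Hypertension screening failure is per-pregnancy (one randomly chosen visit
  loses its blood-pressure measurement), so the screening stage recovers the
  configured compliance instead of its per-visit power.
* Hemoglobin is constant within a pregnancy (one draw per woman, normal with
  the configured mean/sd, clipped to [7.2, 17]; severe cases drawn uniformly
  from [5.5, 6.8] at the floor probability). Within-pregnancy hemoglobin
  drift is *not* modeled; it would blur the closed-form expected prevalence
  the tests check without changing any cascade logic.
* Missingness is field-wise and independent per observation, **except
  tetanus**, which is masked per pregnancy (the whole documentation group):
  the observed record-level missing fractions and the composition
  `coverage = guideline-met × (1 − missingness)` both require record-level
  masking.
* Random-draw order per pregnancy is fixed (sector, booking week, latent
  conditions, compliance flags, clinical values, missingness) so a seed
  identifies a cohort. Dialect degradation uses a separate stream seeded by
  `SeedSequence([seed, 17])` and therefore never perturbs generation draws.

What passing tests on these cohorts do **not** show about real data: no
calendar time, no multiple pregnancies per woman, no facility clustering, no
correlated missingness, no false-positive or false-negative screening tests,
no care-seeking selection. The generator is a statistical scaffold for
validating the cascade and engine logic, not an epidemiological model of the
West Bank.

## 3. Aggregate-source estimators

Routine reports yield `referred / (registered × incidence)` with incidence
supplied externally — in the demo pipeline it is borrowed from the
paper-record cohort's cascade (positives over screened), mirroring how a real
analysis must borrow incidence when routine systems report only counts. Ratios
above 1 (numerator and denominator come from different reporting levels) are
capped at 1.0 with a `SaturationWarning` rather than rejected. The survey
estimator is the effective-coverage crosswalk `contact × quality`, exposed as
a pluggable strategy so a published regression-based indirect estimator can be
substituted without touching callers. The availability map is a pure lookup;
the union over sources covers all eight indicators.

## 4. The lives-saved engine

For cause c and intervention i with effectiveness `Eff_ic`, affected fraction
`AF_ic` and coverage `cov_it`:

```
D*_c      = D_c^2017 / Π_i (1 − Eff_ic · AF_ic · cov_i^2017)      (calibration)
deaths_ct = D*_c × Π_i (1 − Eff_ic · AF_ic · cov_it)              (projection)
```

Anemia: `p_t = p* (1 − Eff·AF·cov_IFA,t)` with `p*` calibrated the same way;
cases = pregnancies per year × `p_t`. Residual risks combine multiplicatively
across interventions (the standard published structure for this model family);
there are no interaction terms, herd effects or uncertainty intervals, and the
population is constant across years (both scenarios share it, so
between-scenario differences are unaffected). Calibration fails loudly when a
factor `(1 − Eff·AF·cov)` is non-positive.

Scenarios: the comparator holds the 2017 national baseline flat through 2025;
the intervention scenario replaces the public-sector component with
`max(target, baseline)` from 2018 — coverage is never scaled *down* by a
scale-up policy. Other-sector coverage is imputed equal to the public baseline
(quality of care assumed constant across sectors), so the national baseline
equals the measured indicator; the national value under scale-up is
`p_public · max(target, baseline) + (1 − p_public) · baseline`. Indicators a
source cannot populate are held identical in both scenarios (their
contribution to averted deaths is structurally zero) and flagged — this is
what produces the attribution signature of each source.

Attribution is computed one intervention at a time (scale only intervention i,
hold the rest at comparator) and normalized to shares. The decomposition is
not additive in general (multiplicative interaction changes sign with the
parameter region), so the sum of one-at-a-time averted deaths is normalized
rather than asserted to bound the joint effect; shares sum to 1 and lie in
[0, 1] whenever anything was averted, and are `None` (never 0/0) otherwise.
Rate changes (MMR per 100,000 live births; NMR per 1,000 live births; SBR per
1,000 total births; anemia in percent) are reported for 2017 and 2025, with
percent change computed both against the scenario's own 2017 value and against
the comparator's 2025 value — the two readings of "% change" a results table
can mean — and rounding happens only at presentation.

The effectiveness/affected-fraction values in `configs/demo.yaml` are
illustrative placeholders on a plausible order of magnitude, clearly labeled;
they are not an authoritative effectiveness database, and every numerical test
sets its own values explicitly.

## 5. Problem sizes and tolerances

The test suite and acceptance script use: n = 2,000 for the full-compliance
limit (exact 1.0 on all five coverage indicators; health status within three
binomial standard errors of the configured prevalences); n = 20,000 for
diabetes-cascade recovery (composite within three standard errors of
0.7 × 0.8 = 0.56, where the SE is the delta-method SE of the two-stage
product — the management stage, with ~1,100 positives, dominates the variance;
a single-binomial SE at n = 20,000 would understate it); 200 random-parameter
cohorts of 5–60 pregnancies for the monotonicity property; 100 random
instances (≤ 3 causes, ≤ 4 interventions) for engine-vs-brute-force agreement
at 1e-10; and cohorts of 1,369 (paper) and 1,800 (eRegistry) pregnancies for
the demo comparison. The brute-force oracle in the tests is coded
independently of the engine (plain-float loops over the closed form).

## 6. Known limitations

* The generator's screening tests have perfect sensitivity and specificity
  conditional on being performed; real cascades lose additional coverage to
  test error, so real composite indicators would be lower still.
* The engine is a deliberately small, transparent model of the
  multiplicative-residual-risk family; it is not a reimplementation of any
  full policy tool (no demographic projection, no default cause structure or
  effectiveness database), and absolute projections carry the illustrative
  epidemiological inputs' uncertainty.
* The indirect survey estimator is the simple crosswalk product; published
  regression-based estimators can be plugged in but are not reimplemented.
* Cross-talk between cascades is real and intended: pre-eclampsia surveillance
  provides the proteinuria tests that also manage mild hypertension, and a
  hospital referral for any reason counts as referral-based management for a
  concurrent positive screen. This mirrors how longitudinal records are
  actually read.
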