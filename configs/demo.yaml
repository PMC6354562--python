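# Four-source demo comparison: routine reports, household survey, paper-based
# records and eRegistry, all feeding the same scale-up question.
#
# The epidemiological block (death envelopes, effectiveness, affected fractions)
# is ILLUSTRATIVE: values are placeholders on the right order of magnitude for a
# West Bank-sized population, not an authoritative effectiveness database.
seed: 1
out_dir: results/demo
target_public: 0.9

# Share of women attending public-sector clinics, per source. The survey carries
# its own estimate; the other three use the routinely reported share.
p_public:
  routine: 0.58
  mics: 0.61
  paper: 0.58
  eregistry: 0.58

thresholds: {}

sources:
  routine:
    # Annual report counts; incidence is borrowed from the paper-record cohort.
    referred_diabetes: 2350
    referred_preeclampsia: 620
    pregnancies_registered: 41000
  mics:
    contact_coverage: 0.95
    quality_fraction:          # facility readiness / quality per indirect indicator
      diabetes_mgmt: 0.37
      htn_mgmt: 0.725
      preeclampsia_mgmt: 0.767
  paper:
    n_pregnancies: 1369        # size of the extracted paper-record cohort
  eregistry:
    n_pregnancies: 1800

epi:
  pregnancies_per_year: 125000
  live_births_per_year: 120000
  maternal_deaths_by_cause:    # ~55/yr -> MMR ~46 per 100,000
    hypertensive_disorders: 15
    maternal_hemorrhage: 20
    maternal_other: 20
  neonatal_deaths_by_cause:    # ~1320/yr -> NMR ~11 per 1,000
    neonatal_tetanus: 6
    prematurity: 700
    neonatal_other: 614
  stillbirths_by_cause:        # ~850/yr -> SBR ~7 per 1,000
    antepartum_stillbirth: 500
    intrapartum_stillbirth: 350
  anemia_prevalence_baseline: 0.27   # model default used when a source lacks anemia data
  effectiveness:               # illustrative relative risk reductions
    preeclampsia_mgmt:
      hypertensive_disorders: 0.58
      antepartum_stillbirth: 0.45
    htn_mgmt:
      hypertensive_disorders: 0.40
    diabetes_mgmt:
      antepartum_stillbirth: 0.10
    tetanus:
      neonatal_tetanus: 0.94
    iron_folate:
      anemia: 0.67
  affected_fraction:           # illustrative shares of each cause the intervention touches
    preeclampsia_mgmt:
      hypertensive_disorders: 0.60
      antepartum_stillbirth: 0.30
    htn_mgmt:
      hypertensive_disorders: 0.40
    diabetes_mgmt:
      antepartum_stillbirth: 0.25
    tetanus:
      neonatal_tetanus: 1.00
    iron_folate:
      anemia: 1.00
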