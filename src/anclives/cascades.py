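"""Effective-coverage cascades over record-level antenatal cohorts.

Each coverage indicator decomposes into stages: of the women eligible for
screening (those attending care), the fraction screened correctly and at the
correct time; of those with a positive screen, the fraction correctly managed.
The composite indicator is the product of the two stage proportions — it equals
correctly managed true positives over the estimated true positives among all
attenders, the quantity a lives-saved model wants as "effective coverage".

Correct management is judged at the clinic: a correct referral counts as correct
management regardless of whether the woman followed through at the referral
facility. Missing screening data is conservatively read as "not screened
correctly" (the record cannot demonstrate guideline care); tetanus and the
health-status indicators additionally offer a complete-case option.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .cohort import Cohort, PregnancyRecord, VisitObservation
from .names import (
    COVERAGE_INDICATORS,
    DIALECTS,
    HEALTH_STATUS_INDICATORS,
    ConfigurationError,
)


@dataclass(frozen=True)
class ClinicalThresholds:
    """Decision boundaries for screening-test interpretation.

    The defaults are the national-guideline values: a glucose challenge above
    140 mg/dl indicates referral, the blood-sugar test belongs in gestational
    weeks 24–28 (closed window), proteinuria qualifies for pre-eclampsia only
    after 20 weeks, anemia is hemoglobin below 11 g/dl (severe below 7), low
    BMI is below 18.5 kg/m² at booking, and hypertension uses the conventional
    140/90 mmHg cut (severe 160/110).
    """

    glucose_challenge_cut: float = 140.0
    blood_sugar_window: tuple[int, int] = (24, 28)
    proteinuria_min_week: int = 20
    anemia_cut: float = 11.0
    severe_anemia_cut: float = 7.0
    low_bmi_cut: float = 18.5
    htn_systolic: int = 140
    htn_diastolic: int = 90
    severe_systolic: int = 160
    severe_diastolic: int = 110
    symptoms_qualify: bool = False  # pre-eclampsia symptoms without proteinuria

    def __post_init__(self) -> None:
        if self.severe_anemia_cut >= self.anemia_cut:
            raise ConfigurationError(
                f"severe_anemia_cut ({self.severe_anemia_cut}) must be below "
                f"anemia_cut ({self.anemia_cut})"
            )
        lo, hi = self.blood_sugar_window
        if lo >= hi:
            raise ConfigurationError(
                f"blood_sugar_window bounds must increase, got {self.blood_sugar_window}"
            )


@dataclass(frozen=True)
class CascadeResult:
    """Counts along eligible ≥ screened correctly ≥ positive ≥ correctly managed."""

    eligible_n: int
    screened_correctly_n: int
    positive_n: int
    correctly_managed_n: int
    coverage: float  # product of stage proportions; 0.0 when undefined
    screening_stage: float  # screened / eligible
    management_stage: float  # managed / positive
    undefined: bool  # no positives (or no eligible): composite has no denominator

    def __post_init__(self) -> None:
        if not (
            self.eligible_n
            >= self.screened_correctly_n
            >= self.positive_n
            >= self.correctly_managed_n
            >= 0
        ):
            raise ValueError(
                "cascade counts must be monotone: "
                f"{self.eligible_n} >= {self.screened_correctly_n} >= "
                f"{self.positive_n} >= {self.correctly_managed_n} >= 0"
            )


def _make_result(eligible: int, screened: int, positive: int, managed: int) -> CascadeResult:
    if eligible == 0 or positive == 0:
        screening = screened / eligible if eligible else 0.0
        return CascadeResult(
            eligible_n=eligible,
            screened_correctly_n=screened,
            positive_n=positive,
            correctly_managed_n=managed,
            coverage=0.0,
            screening_stage=screening,
            management_stage=0.0,
            undefined=True,
        )
    screening = screened / eligible
    management = managed / positive
    return CascadeResult(
        eligible_n=eligible,
        screened_correctly_n=screened,
        positive_n=positive,
        correctly_managed_n=managed,
        coverage=screening * management,
        screening_stage=screening,
        management_stage=management,
        undefined=False,
    )


def _require_dialect(cohort: Cohort) -> None:
    if cohort.dialect not in DIALECTS:
        raise ConfigurationError(
            f"cohort dialect {cohort.dialect!r} not one of {DIALECTS}"
        )


def _is_high_bp(v: VisitObservation, t: ClinicalThresholds) -> bool | None:
    """True/False if measured, None if blood pressure is missing at this visit."""
    if v.systolic_bp is None or v.diastolic_bp is None:
        return None
    return v.systolic_bp >= t.htn_systolic or v.diastolic_bp >= t.htn_diastolic


def _hospital_referred(record: PregnancyRecord) -> bool:
    return any(v.referral == "hospital" for v in record.visits)


def _referred_at_or_after(record: PregnancyRecord, week: int, levels=("high_risk_clinic", "hospital")) -> bool:
    return any(
        v.referral in levels and v.gestational_age >= week for v in record.visits
    )


# --------------------------------------------------------------------------- #
# Diabetes
# --------------------------------------------------------------------------- #

def diabetes_cascade(
    cohort: Cohort, thresholds: ClinicalThresholds = ClinicalThresholds()
) -> CascadeResult:
    """Screening pathway: urine sugar at booking; if not already positive, a blood
    sugar test inside the 24–28-week window; a glucose challenge when the prior
    step is positive. A challenge above the cut is a positive case; correct
    management is referral (to the high-risk clinic or hospital).

    Pregnancies hospital-referred out of primary care before any attended visit
    reaches the window start cannot complete screening and are excluded from the
    eligible pool rather than counted as screening failures.
    """
    _require_dialect(cohort)
    lo, hi = thresholds.blood_sugar_window
    eligible = screened = positive = managed = 0
    for rec in cohort.records:
        if not rec.visits:
            continue
        max_week = max(v.gestational_age for v in rec.visits)
        if _hospital_referred(rec) and max_week < lo:
            continue  # censored out of care before the window opened
        eligible += 1
        booking = rec.visits[0]
        if booking.urine_sugar is None:
            continue
        gct_visit_week = None
        for v in rec.visits:
            if v.glucose_challenge_mgdl is not None:
                gct_visit_week = v.gestational_age
                break
        if booking.urine_sugar == "positive":
            ok = gct_visit_week is not None
        else:
            bs = next(
                (
                    v
                    for v in rec.visits
                    if v.blood_sugar is not None and lo <= v.gestational_age <= hi
                ),
                None,
            )
            if bs is None:
                continue
            ok = bs.blood_sugar != "positive" or gct_visit_week is not None
        if not ok:
            continue
        screened += 1
        gct_value = next(
            (v.glucose_challenge_mgdl for v in rec.visits if v.glucose_challenge_mgdl is not None),
            None,
        )
        if gct_value is not None and gct_value > thresholds.glucose_challenge_cut:
            positive += 1
            if _referred_at_or_after(rec, gct_visit_week):
                managed += 1
    return _make_result(eligible, screened, positive, managed)


# --------------------------------------------------------------------------- #
# Hypertensive disorders
# --------------------------------------------------------------------------- #

def hypertension_cascade(
    cohort: Cohort, thresholds: ClinicalThresholds = ClinicalThresholds()
) -> CascadeResult:
    """Screening requires serial blood pressure at every attended visit. Any
    hypertensive observation is a positive case; correct management is a urine
    protein test for mild gestational hypertension and referral for chronic
    (high-risk clinic or hospital) or moderate/severe (hospital) disease.
    """
    _require_dialect(cohort)
    t = thresholds
    eligible = screened = positive = managed = 0
    for rec in cohort.records:
        if not rec.visits:
            continue
        eligible += 1
        highs = [_is_high_bp(v, t) for v in rec.visits]
        if any(h is None for h in highs):
            continue  # a visit without BP: not serially screened
        screened += 1
        if not any(highs):
            continue
        positive += 1
        first_high_idx = highs.index(True)
        first_high = rec.visits[first_high_idx]
        severe = any(
            v.systolic_bp is not None
            and (v.systolic_bp >= t.severe_systolic or v.diastolic_bp >= t.severe_diastolic)
            for v in rec.visits
        )
        if severe:
            ok = _referred_at_or_after(rec, first_high.gestational_age, levels=("hospital",))
        elif first_high.gestational_age < t.proteinuria_min_week:
            # chronic hypertension: elevated before 20 weeks
            ok = _referred_at_or_after(rec, first_high.gestational_age)
        else:
            # mild gestational hypertension: urine protein testing
            ok = any(
                v.urine_protein is not None
                and v.gestational_age >= first_high.gestational_age
                for v in rec.visits
            )
        if ok:
            managed += 1
    return _make_result(eligible, screened, positive, managed)


# --------------------------------------------------------------------------- #
# Pre-eclampsia
# --------------------------------------------------------------------------- #

def preeclampsia_cascade(
    cohort: Cohort, thresholds: ClinicalThresholds = ClinicalThresholds()
) -> CascadeResult:
    """Screening is a urine protein test following a hypertensive blood-pressure
    measurement after 20 weeks (at every such visit); hypertension with
    proteinuria after 20 weeks is a positive case; correct management is hospital
    referral. Referral censoring is honored: the referral visit itself carries
    the management event even though later visits are absent, and pregnancies
    censored out of primary care at or before 20 weeks (hospital-referred, e.g.
    for severe hypertension) are excluded from the eligible pool — they cannot
    be screened at the correct time at the clinic.
    """
    _require_dialect(cohort)
    t = thresholds
    eligible = screened = positive = managed = 0
    for rec in cohort.records:
        if not rec.visits:
            continue
        max_week = max(v.gestational_age for v in rec.visits)
        if _hospital_referred(rec) and max_week <= t.proteinuria_min_week:
            continue
        eligible += 1
        late = [v for v in rec.visits if v.gestational_age > t.proteinuria_min_week]
        measured = [v for v in late if _is_high_bp(v, t) is not None]
        if not measured:
            continue  # no post-20-week blood pressure at all
        high = [v for v in measured if _is_high_bp(v, t)]
        if any(v.urine_protein is None for v in high):
            continue  # hypertension seen but proteinuria not checked
        screened += 1
        pos_visits = [
            v
            for v in high
            if v.urine_protein == "positive"
            or (t.symptoms_qualify and v.pe_symptoms)
        ]
        if not pos_visits:
            continue
        positive += 1
        first = min(pos_visits, key=lambda v: v.gestational_age)
        if _referred_at_or_after(rec, first.gestational_age, levels=("hospital",)):
            managed += 1
    return _make_result(eligible, screened, positive, managed)


# --------------------------------------------------------------------------- #
# Tetanus and iron-folate
# --------------------------------------------------------------------------- #

def tetanus_coverage(
    cohort: Cohort, dialect: str | None = None, missing_policy: str = "conservative"
) -> float:
    """Proportion vaccinated according to guidelines.

    Paper dialect: immune at entry, or any documented dose. eRegistry dialect:
    enrollment status documented AND (immune, or a booster/dose given when
    unknown/unimmunized). Under the conservative policy, pregnancies with
    missing vaccination data stay in the denominator as unvaccinated;
    ``missing_policy='complete_case'`` drops them instead.
    """
    dialect = dialect or cohort.dialect
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    num = den = 0
    for rec in cohort.records:
        status = rec.visits[0].tetanus_entry_status if rec.visits else None
        dosed = any(v.tetanus_dose_given for v in rec.visits)
        documented = status is not None or dosed
        if not documented and missing_policy == "complete_case":
            continue
        den += 1
        if dialect == "paper":
            vaccinated = status == "immune" or dosed
        else:
            vaccinated = status is not None and (status == "immune" or dosed)
        if vaccinated:
            num += 1
    return num / den if den else 0.0


def iron_folate_coverage(
    cohort: Cohort,
    dialect: str | None = None,
    thresholds: ClinicalThresholds = ClinicalThresholds(),
) -> float:
    """Paper dialect: the single-checkbox proportion (any supplement given).
    eRegistry dialect: proportion correctly supplemented given anemia status —
    anemic women (any recorded hemoglobin below the cut) need a treatment dose
    recorded, non-anemic women a routine dose — pooled over the cohort.
    """
    dialect = dialect or cohort.dialect
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    num = den = 0
    for rec in cohort.records:
        den += 1
        if dialect == "paper":
            if any(v.iron_folate is True for v in rec.visits):
                num += 1
        else:
            anemic = any(
                v.hemoglobin is not None and v.hemoglobin < thresholds.anemia_cut
                for v in rec.visits
            )
            wanted = "treatment" if anemic else "routine"
            if any(v.iron_folate == wanted for v in rec.visits):
                num += 1
    return num / den if den else 0.0


# --------------------------------------------------------------------------- #
# Health status
# --------------------------------------------------------------------------- #

def health_status_indicators(
    cohort: Cohort,
    thresholds: ClinicalThresholds = ClinicalThresholds(),
    missing_policy: str = "conservative",
) -> dict[str, float]:
    """Anemia (any attended-visit hemoglobin below the cut), severe anemia
    (likewise, severe cut) and low BMI at the booking visit. Strict ``<`` at
    every cut. Severe anemia can never exceed anemia.
    """
    n = anemia = severe = low_bmi = 0
    n_bmi = 0
    for rec in cohort.records:
        hbs = [v.hemoglobin for v in rec.visits if v.hemoglobin is not None]
        if hbs or missing_policy == "conservative":
            n += 1
            if hbs and min(hbs) < thresholds.anemia_cut:
                anemia += 1
            if hbs and min(hbs) < thresholds.severe_anemia_cut:
                severe += 1
        bmi = rec.visits[0].bmi if rec.visits else None
        if bmi is not None or missing_policy == "conservative":
            n_bmi += 1
            if bmi is not None and bmi < thresholds.low_bmi_cut:
                low_bmi += 1
    return {
        "anemia": anemia / n if n else 0.0,
        "severe_anemia": severe / n if n else 0.0,
        "low_bmi": low_bmi / n_bmi if n_bmi else 0.0,
    }


# --------------------------------------------------------------------------- #
# Assembly
# --------------------------------------------------------------------------- #

@dataclass
class IndicatorSet:
    """The five coverage and three health-status indicators for one source/year.

    ``None`` marks an indicator the source cannot populate (never silently 0);
    ``availability`` tags each as direct / indirect / unavailable.
    """

    source_dialect: str
    year: int
    coverage: dict = field(default_factory=dict)
    health_status: dict = field(default_factory=dict)
    availability: dict = field(default_factory=dict)
    cascades: dict = field(default_factory=dict)  # CascadeResult per cascade indicator

    def __post_init__(self) -> None:
        for name, value in list(self.coverage.items()) + list(self.health_status.items()):
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"indicator {name!r} outside [0, 1]: {value}")


def indicator_set(
    cohort: Cohort,
    dialect: str | None = None,
    thresholds: ClinicalThresholds = ClinicalThresholds(),
    year: int = 2017,
) -> IndicatorSet:
    """All eight indicators from a record-level cohort (both record dialects
    supply all eight directly; availability gaps belong to aggregate sources).
    """
    dialect = dialect or cohort.dialect
    dia = diabetes_cascade(cohort, thresholds)
    htn = hypertension_cascade(cohort, thresholds)
    pe = preeclampsia_cascade(cohort, thresholds)
    coverage = {
        "diabetes_mgmt": dia.coverage,
        "htn_mgmt": htn.coverage,
        "preeclampsia_mgmt": pe.coverage,
        "tetanus": tetanus_coverage(cohort, dialect),
        "iron_folate": iron_folate_coverage(cohort, dialect, thresholds),
    }
    return IndicatorSet(
        source_dialect=dialect,
        year=year,
        coverage=coverage,
        health_status=health_status_indicators(cohort, thresholds),
        availability={name: "direct" for name in COVERAGE_INDICATORS + HEALTH_STATUS_INDICATORS},
        cascades={"diabetes_mgmt": dia, "htn_mgmt": htn, "preeclampsia_mgmt": pe},
    )
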