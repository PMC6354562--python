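"""Synthetic longitudinal antenatal cohorts.

Generates seeded per-pregnancy visit histories with the statistical structure the
effective-coverage cascades assume: latent clinical conditions (gestational diabetes,
chronic / gestational hypertension, pre-eclampsia, anemia, low BMI, tetanus immunity)
that surface in the observed record *only* through the guideline screening pathway —
a latent diabetic shows a glucose challenge above the referral cut only when the test
was actually performed, a hypertensive shows elevated blood pressure only at visits
where it was measured, and so on.

Two record dialects are supported. The richer ``eregistry`` structure (dose-specific
iron-folate documentation, enrollment tetanus status plus boosters, low missingness)
is generated natively; :func:`degrade_to_dialect` collapses it to the ``paper``
structure (single iron-folate checkbox, heavier tetanus missingness). Hospital
referral censoring — women referred to hospital do not return to the primary-care
clinic — is a separate explicit step, :func:`apply_referral_censoring`.

Random-number usage order is fixed per pregnancy (sector, booking week, latent
conditions, compliance flags, clinical values, missingness masks, in that order) so a
seed identifies a cohort across versions.
"""
from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .names import DIALECTS, ConfigurationError

SCHEMA_VERSION = "1"

HTN_NONE = "none"
HTN_CHRONIC = "chronic"
HTN_GEST_MILD = "gest_mild"
HTN_GEST_MODSEV = "gest_modsev"

REFERRAL_LEVELS = ("none", "high_risk_clinic", "hospital")

_DEF_SCREENING = {"diabetes": 0.40, "hypertension": 0.50, "preeclampsia": 0.60}
_DEF_MANAGEMENT = {
    "diabetes": 0.25,
    "hypertension": 0.70,
    "preeclampsia": 0.13,
    "tetanus": 0.85,
}
_DEF_MISSINGNESS = {"tetanus": 0.07, "tetanus_paper": 0.42}
_DEF_SCHEDULE = (12, 16, 20, 24, 26, 30, 34, 38)


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration.

    Defaults emulate the conditions of a West Bank public-sector antenatal cohort:
    1369 pregnancies (the size of the extracted paper-record cohort), condition
    frequencies in the range clinical registries report for this population, and
    screening/management compliances that land the composite coverage indicators in
    the low double digits for the three cascade indicators and the high double
    digits for tetanus and iron-folate.
    """

    n_pregnancies: int = 1369
    incidence_diabetes: float = 0.08
    incidence_chronic_htn: float = 0.01
    incidence_gest_htn_mild: float = 0.04
    incidence_gest_htn_modsev: float = 0.02
    incidence_preeclampsia: float = 0.03
    anemia_hb_mean: float = 11.4
    anemia_hb_sd: float = 1.2
    severe_anemia_floor: float = 0.001
    low_bmi_prob: float = 0.035
    tetanus_immune_at_entry_prob: float = 0.5
    screening_compliance: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_SCREENING)
    )
    management_compliance: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_MANAGEMENT)
    )
    iron_folate_given_prob: float = 0.64
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_MISSINGNESS)
    )
    visit_schedule: Sequence[int] = _DEF_SCHEDULE
    booking_week_range: tuple[int, int] = (8, 16)
    public_sector_prob: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")

        if self.n_pregnancies < 1:
            raise ConfigurationError(
                f"n_pregnancies must be >= 1, got {self.n_pregnancies!r}"
            )
        for name in (
            "incidence_diabetes",
            "incidence_chronic_htn",
            "incidence_gest_htn_mild",
            "incidence_gest_htn_modsev",
            "incidence_preeclampsia",
            "severe_anemia_floor",
            "low_bmi_prob",
            "tetanus_immune_at_entry_prob",
            "iron_folate_given_prob",
            "public_sector_prob",
        ):
            _prob(name, getattr(self, name))
        htn_total = (
            self.incidence_chronic_htn
            + self.incidence_gest_htn_mild
            + self.incidence_gest_htn_modsev
        )
        if htn_total > 1.0:
            raise ConfigurationError(
                "hypertension incidences sum above 1: "
                f"incidence_chronic_htn + incidence_gest_htn_mild + "
                f"incidence_gest_htn_modsev = {htn_total}"
            )
        if self.incidence_preeclampsia > htn_total + 1e-12:
            raise ConfigurationError(
                "incidence_preeclampsia must not exceed the summed hypertension "
                f"incidences ({htn_total}); got {self.incidence_preeclampsia}"
            )
        for mapping, name in (
            (self.screening_compliance, "screening_compliance"),
            (self.management_compliance, "management_compliance"),
            (self.missingness, "missingness"),
        ):
            for key, value in mapping.items():
                _prob(f"{name}[{key!r}]", value)
        if len(self.visit_schedule) == 0:
            raise ConfigurationError("visit_schedule must not be empty")
        weeks = list(self.visit_schedule)
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigurationError(
                f"visit_schedule must be strictly increasing, got {weeks}"
            )
        if weeks[-1] > 44:
            raise ConfigurationError(
                f"visit_schedule weeks must be <= 44, got {weeks[-1]}"
            )
        lo, hi = self.booking_week_range
        if not (4 <= lo <= hi <= 44):
            raise ConfigurationError(
                f"booking_week_range must satisfy 4 <= lo <= hi <= 44, "
                f"got {self.booking_week_range!r}"
            )
        if self.anemia_hb_sd <= 0:
            raise ConfigurationError(
                f"anemia_hb_sd must be positive, got {self.anemia_hb_sd!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["screening_compliance"] = dict(self.screening_compliance)
        d["management_compliance"] = dict(self.management_compliance)
        d["missingness"] = dict(self.missingness)
        d["visit_schedule"] = list(self.visit_schedule)
        d["booking_week_range"] = list(self.booking_week_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortParams":
        d = dict(d)
        if "visit_schedule" in d:
            d["visit_schedule"] = tuple(d["visit_schedule"])
        if "booking_week_range" in d:
            d["booking_week_range"] = tuple(d["booking_week_range"])
        return cls(**d)


@dataclass(frozen=True)
class LatentTruth:
    """Ground-truth condition flags; synthetic output only, never read by indicators."""

    diabetes: bool
    htn_category: str  # none / chronic / gest_mild / gest_modsev
    htn_onset_week: int | None
    preeclampsia: bool
    pe_onset_week: int | None
    tetanus_immune_at_entry: bool
    anemic: bool
    severe_anemic: bool
    low_bmi: bool


@dataclass
class VisitObservation:
    pregnancy_id: str
    gestational_age: int
    urine_sugar: str | None = None  # negative / positive / None (not done or missing)
    blood_sugar: str | None = None  # negative / positive / None
    glucose_challenge_mgdl: float | None = None
    systolic_bp: int | None = None
    diastolic_bp: int | None = None
    urine_protein: str | None = None  # negative / positive / None
    hemoglobin: float | None = None
    bmi: float | None = None  # booking visit only
    tetanus_entry_status: str | None = None  # immune / unimmunized / None; booking only
    tetanus_dose_given: bool | None = None
    iron_folate: object = None  # eregistry: none/routine/treatment; paper: bool; None = missing
    pe_symptoms: bool | None = None  # optional symptom flag; generator leaves it unset
    referral: str = "none"


@dataclass
class PregnancyRecord:
    pregnancy_id: str
    sector: str  # public / other
    booking_week: int
    visits: list[VisitObservation]
    latent_truth: LatentTruth | None = None


@dataclass
class Cohort:
    """A record collection plus the parameters and dialect that produced it."""

    records: list[PregnancyRecord]
    params: CohortParams
    dialect: str = "eregistry"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def generate_cohort(params: CohortParams) -> Cohort:
    """Draw a synthetic cohort in the native (eRegistry-structured) dialect.

    Deterministic in ``params`` (including ``params.seed``). Latent condition
    frequencies converge to the configured incidences as ``n_pregnancies`` grows.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sc = params.screening_compliance
    mc = params.management_compliance
    miss = params.missingness
    htn_total = (
        params.incidence_chronic_htn
        + params.incidence_gest_htn_mild
        + params.incidence_gest_htn_modsev
    )
    pe_given_htn = (
        params.incidence_preeclampsia / htn_total if htn_total > 0 else 0.0
    )
    lo, hi = params.booking_week_range
    width = len(str(params.n_pregnancies))

    records: list[PregnancyRecord] = []
    for i in range(params.n_pregnancies):
        pid = f"P{i:0{width}d}"
        sector = "public" if rng.random() < params.public_sector_prob else "other"
        booking = int(rng.integers(lo, hi + 1))
        weeks = [booking] + [w for w in params.visit_schedule if w > booking]

        # -- latent conditions -------------------------------------------------
        diabetic = rng.random() < params.incidence_diabetes
        u = rng.random()
        if u < params.incidence_chronic_htn:
            cat = HTN_CHRONIC
        elif u < params.incidence_chronic_htn + params.incidence_gest_htn_mild:
            cat = HTN_GEST_MILD
        elif u < htn_total:
            cat = HTN_GEST_MODSEV
        else:
            cat = HTN_NONE
        if cat == HTN_CHRONIC:
            onset: int | None = 0
        elif cat in (HTN_GEST_MILD, HTN_GEST_MODSEV):
            onset = int(rng.integers(20, 33))
        else:
            onset = None
        pe = cat != HTN_NONE and rng.random() < pe_given_htn
        pe_onset = int(rng.integers(max(21, (onset or 20) + 1), 37)) if pe else None
        immune = rng.random() < params.tetanus_immune_at_entry_prob
        tet_dosed = (not immune) and rng.random() < mc.get("tetanus", 1.0)
        severe = rng.random() < params.severe_anemia_floor
        if severe:
            hb = float(rng.uniform(5.5, 6.8))
        else:
            hb = float(
                np.clip(rng.normal(params.anemia_hb_mean, params.anemia_hb_sd), 7.2, 17.0)
            )
        low_bmi = rng.random() < params.low_bmi_prob
        bmi = float(rng.uniform(16.0, 18.4)) if low_bmi else float(rng.uniform(19.5, 34.0))

        # -- per-pregnancy compliance flags -----------------------------------
        d_screen = rng.random() < sc.get("diabetes", 1.0)
        d_manage = rng.random() < mc.get("diabetes", 1.0)
        h_screen = rng.random() < sc.get("hypertension", 1.0)
        h_manage = rng.random() < mc.get("hypertension", 1.0)
        p_screen = rng.random() < sc.get("preeclampsia", 1.0)
        p_manage = rng.random() < mc.get("preeclampsia", 1.0)
        iron_given = rng.random() < params.iron_folate_given_prob
        bp_drop_idx = -1 if h_screen else int(rng.integers(0, len(weeks)))
        gct = float(max(145.0, rng.normal(172.0, 14.0))) if diabetic else None
        tetanus_masked = rng.random() < miss.get("tetanus", 0.0)
        anemic_true = hb < 11.0

        # -- assemble visits ---------------------------------------------------
        visits: list[VisitObservation] = []
        htn_detected = False
        pe_detected = False
        bs_done = False
        for j, wk in enumerate(weeks):
            v = VisitObservation(pregnancy_id=pid, gestational_age=wk)
            is_booking = j == 0
            if is_booking:
                v.urine_sugar = "negative"  # urine sugar is insensitive here; the
                # pathway detects diabetics through the blood-sugar step
                v.bmi = bmi
                if not tetanus_masked:
                    v.tetanus_entry_status = "immune" if immune else "unimmunized"
            if d_screen and not bs_done and 24 <= wk <= 28:
                bs_done = True
                if diabetic:
                    v.blood_sugar = "positive"
                    v.glucose_challenge_mgdl = gct
                    if d_manage:
                        v.referral = "high_risk_clinic"
                else:
                    v.blood_sugar = "negative"
            hyper_now = cat == HTN_CHRONIC or (
                cat in (HTN_GEST_MILD, HTN_GEST_MODSEV) and wk >= onset
            )
            measure_bp = j != bp_drop_idx
            if measure_bp:
                if not hyper_now:
                    sys = int(np.clip(rng.normal(112, 8), 85, 135))
                    dia = int(np.clip(rng.normal(70, 6), 50, 85))
                elif cat == HTN_GEST_MODSEV:
                    sys = int(np.clip(rng.normal(166, 5), 161, 200))
                    dia = int(np.clip(rng.normal(112, 4), 111, 130))
                else:  # chronic or mild gestational: non-severe hypertensive range
                    sys = int(np.clip(rng.normal(147, 4), 141, 158))
                    dia = int(np.clip(rng.normal(95, 3), 91, 104))
                v.systolic_bp, v.diastolic_bp = sys, dia
            if measure_bp and hyper_now and not htn_detected:
                htn_detected = True
                if h_manage:
                    if cat == HTN_CHRONIC and v.referral == "none":
                        v.referral = "high_risk_clinic"
                    elif cat == HTN_GEST_MODSEV:
                        v.referral = "hospital"
                    elif cat == HTN_GEST_MILD:
                        v.urine_protein = (
                            "positive" if pe and wk >= pe_onset else "negative"
                        )
            # serial pre-eclampsia surveillance among hypertensives after 20 wk
            if (
                measure_bp
                and hyper_now
                and wk > 20
                and p_screen
                and v.urine_protein is None
            ):
                v.urine_protein = "positive" if pe and wk >= pe_onset else "negative"
            if v.urine_protein == "positive" and not pe_detected:
                pe_detected = True
                if p_manage:
                    v.referral = "hospital"
            v.hemoglobin = hb
            if (not tetanus_masked) and tet_dosed and j in (0, 1):
                v.tetanus_dose_given = True
            if iron_given:
                v.iron_folate = "treatment" if anemic_true else "routine"
            else:
                v.iron_folate = "none"
            _apply_field_missingness(v, rng, miss, is_booking)
            visits.append(v)

        truth = LatentTruth(
            diabetes=diabetic,
            htn_category=cat,
            htn_onset_week=onset,
            preeclampsia=pe,
            pe_onset_week=pe_onset,
            tetanus_immune_at_entry=immune,
            anemic=anemic_true,
            severe_anemic=severe,
            low_bmi=low_bmi,
        )
        records.append(
            PregnancyRecord(
                pregnancy_id=pid,
                sector=sector,
                booking_week=booking,
                visits=visits,
                latent_truth=truth,
            )
        )
    return Cohort(records=records, params=params, dialect="eregistry")


_MASKABLE_FIELDS = (
    "urine_sugar",
    "blood_sugar",
    "glucose_challenge_mgdl",
    "urine_protein",
    "hemoglobin",
    "iron_folate",
)


def _apply_field_missingness(
    v: VisitObservation, rng: np.random.Generator, miss: Mapping[str, float], booking: bool
) -> None:
    """Field-wise, per-observation missingness (tetanus is masked per pregnancy)."""
    for name in _MASKABLE_FIELDS:
        p = miss.get(name, 0.0)
        if p > 0 and getattr(v, name) is not None and rng.random() < p:
            setattr(v, name, None)
    p = miss.get("blood_pressure", 0.0)
    if p > 0 and v.systolic_bp is not None and rng.random() < p:
        v.systolic_bp = None
        v.diastolic_bp = None
    if booking:
        p = miss.get("bmi", 0.0)
        if p > 0 and v.bmi is not None and rng.random() < p:
            v.bmi = None


def _copy_record(record: PregnancyRecord) -> PregnancyRecord:
    return PregnancyRecord(
        pregnancy_id=record.pregnancy_id,
        sector=record.sector,
        booking_week=record.booking_week,
        visits=[dataclasses.replace(v) for v in record.visits],
        latent_truth=record.latent_truth,
    )


def degrade_to_dialect(cohort: Cohort, dialect: str) -> Cohort:
    """Re-encode a natively generated cohort in a record dialect.

    ``eregistry`` is the identity. ``paper`` collapses dose-specific iron-folate
    documentation to a single given / not-given checkbox and applies the heavier
    paper-record tetanus missingness (configured as ``missingness['tetanus_paper']``,
    applied incrementally on top of the base rate so the marginal missing fraction
    matches the configured one). Pregnancy count and visit timing never change.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {DIALECTS}"
        )
    if dialect == cohort.dialect:
        return Cohort(
            records=[_copy_record(r) for r in cohort.records],
            params=cohort.params,
            dialect=cohort.dialect,
        )
    if dialect == "eregistry":
        raise ConfigurationError(
            "cannot upgrade a paper-dialect cohort back to eregistry"
        )

    miss = cohort.params.missingness
    base = miss.get("tetanus", 0.0)
    target = miss.get("tetanus_paper", base)
    extra = 0.0 if base >= 1.0 else max(0.0, (target - base) / (1.0 - base))
    # Dedicated stream so dialect degradation never perturbs generation draws.
    rng = np.random.default_rng(np.random.SeedSequence([int(cohort.params.seed), 17]))

    records = []
    for record in cohort.records:
        rec = _copy_record(record)
        mask_tetanus = rng.random() < extra
        for v in rec.visits:
            if v.iron_folate is not None:
                v.iron_folate = v.iron_folate in ("routine", "treatment")
            if mask_tetanus:
                v.tetanus_entry_status = None
                v.tetanus_dose_given = None
        records.append(rec)
    return Cohort(records=records, params=cohort.params, dialect="paper")


def apply_referral_censoring(cohort: Cohort) -> Cohort:
    """Drop all visits after a pregnancy's first hospital referral.

    Women referred to hospital do not return to the primary-care clinic; the
    referral visit itself is kept (it carries the referral event the management
    stages count). Idempotent; never increases visit counts.
    """
    records = []
    for record in cohort.records:
        rec = _copy_record(record)
        for idx, v in enumerate(rec.visits):
            if v.referral == "hospital":
                rec.visits = rec.visits[: idx + 1]
                break
        records.append(rec)
    return Cohort(records=records, params=cohort.params, dialect=cohort.dialect)


# --------------------------------------------------------------------------- #
# CSV round-trip: one row per visit observation, sidecar JSON with params.
# --------------------------------------------------------------------------- #

_VISIT_COLUMNS = (
    "pregnancy_id",
    "sector",
    "booking_week",
    "gestational_age",
    "urine_sugar",
    "blood_sugar",
    "glucose_challenge_mgdl",
    "systolic_bp",
    "diastolic_bp",
    "urine_protein",
    "hemoglobin",
    "bmi",
    "tetanus_entry_status",
    "tetanus_dose_given",
    "iron_folate",
    "pe_symptoms",
    "referral",
)
_TRUTH_COLUMNS = (
    "truth_diabetes",
    "truth_htn_category",
    "truth_htn_onset_week",
    "truth_preeclampsia",
    "truth_pe_onset_week",
    "truth_tetanus_immune_at_entry",
    "truth_anemic",
    "truth_severe_anemic",
    "truth_low_bmi",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(s: str) -> bool | None:
    return None if s == "" else s == "true"


def write_cohort_csv(cohort: Cohort, path: str | Path, with_truth: bool = False) -> None:
    """Write one row per visit; empty field = missing; sidecar ``<path>.meta.json``.

    Floats are written with full ``repr`` precision so the round-trip is bit-exact.
    Latent-truth columns are emitted only when ``with_truth`` is set, keeping
    indicator inputs honest by default.
    """
    path = Path(path)
    columns = _VISIT_COLUMNS + (_TRUTH_COLUMNS if with_truth else ())
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in cohort.records:
            for v in rec.visits:
                row = [
                    rec.pregnancy_id,
                    rec.sector,
                    rec.booking_week,
                    v.gestational_age,
                    _fmt(v.urine_sugar),
                    _fmt(v.blood_sugar),
                    _fmt(v.glucose_challenge_mgdl),
                    _fmt(v.systolic_bp),
                    _fmt(v.diastolic_bp),
                    _fmt(v.urine_protein),
                    _fmt(v.hemoglobin),
                    _fmt(v.bmi),
                    _fmt(v.tetanus_entry_status),
                    _fmt(v.tetanus_dose_given),
                    _fmt(v.iron_folate),
                    _fmt(v.pe_symptoms),
                    v.referral,
                ]
                if with_truth:
                    t = rec.latent_truth
                    if t is None:
                        row += [""] * len(_TRUTH_COLUMNS)
                    else:
                        row += [
                            _fmt(t.diabetes),
                            t.htn_category,
                            _fmt(t.htn_onset_week),
                            _fmt(t.preeclampsia),
                            _fmt(t.pe_onset_week),
                            _fmt(t.tetanus_immune_at_entry),
                            _fmt(t.anemic),
                            _fmt(t.severe_anemic),
                            _fmt(t.low_bmi),
                        ]
                writer.writerow(row)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "dialect": cohort.dialect,
        "with_truth": with_truth,
        "params": cohort.params.to_dict(),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_cohort_csv(path: str | Path) -> Cohort:
    """Inverse of :func:`write_cohort_csv`; ``read(write(x)) == x`` on schema fields."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    dialect = meta["dialect"]
    with_truth = meta.get("with_truth", False)
    params = CohortParams.from_dict(meta["params"])

    records: dict[str, PregnancyRecord] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _VISIT_COLUMNS if c not in header]
        if missing:
            from .names import SchemaError

            raise SchemaError(f"cohort CSV is missing required column(s): {missing}")
        for row in reader:
            pid = row["pregnancy_id"]
            if pid not in records:
                truth = None
                if with_truth and row.get("truth_htn_category", "") != "":
                    truth = LatentTruth(
                        diabetes=_parse_bool(row["truth_diabetes"]),
                        htn_category=row["truth_htn_category"],
                        htn_onset_week=(
                            int(row["truth_htn_onset_week"])
                            if row["truth_htn_onset_week"] != ""
                            else None
                        ),
                        preeclampsia=_parse_bool(row["truth_preeclampsia"]),
                        pe_onset_week=(
                            int(row["truth_pe_onset_week"])
                            if row["truth_pe_onset_week"] != ""
                            else None
                        ),
                        tetanus_immune_at_entry=_parse_bool(
                            row["truth_tetanus_immune_at_entry"]
                        ),
                        anemic=_parse_bool(row["truth_anemic"]),
                        severe_anemic=_parse_bool(row["truth_severe_anemic"]),
                        low_bmi=_parse_bool(row["truth_low_bmi"]),
                    )
                records[pid] = PregnancyRecord(
                    pregnancy_id=pid,
                    sector=row["sector"],
                    booking_week=int(row["booking_week"]),
                    visits=[],
                    latent_truth=truth,
                )
            iron_raw = row["iron_folate"]
            if iron_raw == "":
                iron = None
            elif dialect == "paper":
                iron = iron_raw == "true"
            else:
                iron = iron_raw
            records[pid].visits.append(
                VisitObservation(
                    pregnancy_id=pid,
                    gestational_age=int(row["gestational_age"]),
                    urine_sugar=row["urine_sugar"] or None,
                    blood_sugar=row["blood_sugar"] or None,
                    glucose_challenge_mgdl=(
                        float(row["glucose_challenge_mgdl"])
                        if row["glucose_challenge_mgdl"] != ""
                        else None
                    ),
                    systolic_bp=(
                        int(row["systolic_bp"]) if row["systolic_bp"] != "" else None
                    ),
                    diastolic_bp=(
                        int(row["diastolic_bp"]) if row["diastolic_bp"] != "" else None
                    ),
                    urine_protein=row["urine_protein"] or None,
                    hemoglobin=(
                        float(row["hemoglobin"]) if row["hemoglobin"] != "" else None
                    ),
                    bmi=float(row["bmi"]) if row["bmi"] != "" else None,
                    tetanus_entry_status=row["tetanus_entry_status"] or None,
                    tetanus_dose_given=_parse_bool(row["tetanus_dose_given"]),
                    iron_folate=iron,
                    pe_symptoms=_parse_bool(row["pe_symptoms"]),
                    referral=row["referral"],
                )
            )
    return Cohort(records=list(records.values()), params=params, dialect=dialect)
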