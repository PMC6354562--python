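"""Shared builders for hand-enumerated cascade fixtures.

The expected counts for every fixture were enumerated by hand from the cascade
definitions before the cascades were implemented; tests assert those frozen
values exactly.
"""
from __future__ import annotations

import pytest

from anclives import Cohort, CohortParams, PregnancyRecord, VisitObservation


def visit(pid: str, week: int, **kw) -> VisitObservation:
    return VisitObservation(pregnancy_id=pid, gestational_age=week, **kw)


def record(pid: str, visits: list[VisitObservation], sector: str = "public") -> PregnancyRecord:
    return PregnancyRecord(
        pregnancy_id=pid, sector=sector, booking_week=visits[0].gestational_age, visits=visits
    )


def cohort(records: list[PregnancyRecord], dialect: str = "eregistry") -> Cohort:
    return Cohort(
        records=records,
        params=CohortParams(n_pregnancies=max(1, len(records))),
        dialect=dialect,
    )


@pytest.fixture
def full_compliance_params() -> CohortParams:
    """Perfect screening/management, no missingness: coverage limits must be 1.0."""
    return CohortParams(
        n_pregnancies=300,
        seed=1,
        screening_compliance={"diabetes": 1.0, "hypertension": 1.0, "preeclampsia": 1.0},
        management_compliance={
            "diabetes": 1.0,
            "hypertension": 1.0,
            "preeclampsia": 1.0,
            "tetanus": 1.0,
        },
        iron_folate_given_prob=1.0,
        missingness={},
    )


@pytest.fixture
def diabetes_fixture() -> Cohort:
    """12 pregnancies: 2 true diabetics (both screened, 1 referred), 1 woman with
    a late blood-sugar test (outside 24-28 wk), 9 correctly screened negatives.

    Hand enumeration: eligible 12, screened correctly 11 (the late tester fails),
    positive 2, managed 1 -> coverage (11/12) * (1/2) = 11/24.
    """
    recs = [
        record(
            "D01",
            [
                visit("D01", 10, urine_sugar="negative"),
                visit("D01", 25, blood_sugar="positive", glucose_challenge_mgdl=180.0,
                      referral="high_risk_clinic"),
                visit("D01", 30),
            ],
        ),
        record(
            "D02",
            [
                visit("D02", 10, urine_sugar="negative"),
                visit("D02", 25, blood_sugar="positive", glucose_challenge_mgdl=175.0),
                visit("D02", 30),
            ],
        ),
        record(
            "D03",
            [
                visit("D03", 10, urine_sugar="negative"),
                visit("D03", 25),
                visit("D03", 30, blood_sugar="negative"),  # late: outside the window
            ],
        ),
    ]
    for i in range(4, 13):
        pid = f"D{i:02d}"
        recs.append(
            record(
                pid,
                [
                    visit(pid, 10, urine_sugar="negative"),
                    visit(pid, 25, blood_sugar="negative"),
                    visit(pid, 30),
                ],
            )
        )
    return cohort(recs)


def _bp(pid: str, week: int, sys: int | None, dia: int | None, **kw) -> VisitObservation:
    return visit(pid, week, systolic_bp=sys, diastolic_bp=dia, **kw)


@pytest.fixture
def hypertension_fixture() -> Cohort:
    """10 pregnancies, 3 hypertensive, 1 mild case without a proteinuria test.

    Hand enumeration: eligible 10; screened 9 (one woman misses blood pressure at
    a visit); positive 3 (chronic + severe + mild); managed 2 (the mild case has
    no urine protein test) -> coverage (9/10) * (2/3) = 0.6.
    """
    recs = [
        record(  # chronic: elevated from booking, referred to high-risk clinic
            "H01",
            [
                _bp("H01", 10, 150, 95, referral="high_risk_clinic"),
                _bp("H01", 22, 150, 95),
                _bp("H01", 30, 151, 96),
            ],
        ),
        record(  # moderate/severe gestational: hospital referral, censored after
            "H02",
            [_bp("H02", 10, 115, 70), _bp("H02", 22, 165, 112, referral="hospital")],
        ),
        record(  # mild gestational without urine protein testing: unmanaged
            "H03",
            [_bp("H03", 10, 115, 70), _bp("H03", 22, 145, 92), _bp("H03", 30, 146, 93)],
        ),
        record(  # blood pressure skipped at one visit: not serially screened
            "H04",
            [_bp("H04", 10, 115, 70), _bp("H04", 22, None, None), _bp("H04", 30, 114, 71)],
        ),
    ]
    for i in range(5, 11):
        pid = f"H{i:02d}"
        recs.append(
            record(pid, [_bp(pid, 10, 112, 70), _bp(pid, 22, 113, 72), _bp(pid, 30, 111, 69)])
        )
    return cohort(recs)


@pytest.fixture
def preeclampsia_fixture() -> Cohort:
    """8 pregnancies; 2 pre-eclamptic (1 referred to hospital, 1 kept at clinic).

    Hand enumeration: eligible 8; screened 6 (one woman has no post-20-week blood
    pressure, one hypertensive was never proteinuria-tested); positive 2;
    managed 1 -> coverage (6/8) * (1/2) = 0.375.
    """
    recs = [
        record(  # pre-eclamptic, detected at 26 wk, hospital-referred (censored)
            "P1",
            [
                _bp("P1", 10, 110, 70),
                _bp("P1", 22, 150, 95, urine_protein="negative"),
                _bp("P1", 26, 150, 95, urine_protein="positive", referral="hospital"),
            ],
        ),
        record(  # pre-eclamptic kept at the clinic: positive but unmanaged
            "P2",
            [
                _bp("P2", 10, 110, 70),
                _bp("P2", 22, 148, 94, urine_protein="negative"),
                _bp("P2", 26, 149, 95, urine_protein="positive"),
                _bp("P2", 30, 150, 96, urine_protein="positive"),
            ],
        ),
        record(  # chronic hypertensive, proteinuria serially negative
            "P3",
            [
                _bp("P3", 10, 150, 95, referral="high_risk_clinic"),
                _bp("P3", 22, 150, 95, urine_protein="negative"),
                _bp("P3", 26, 151, 94, urine_protein="negative"),
                _bp("P3", 30, 150, 95, urine_protein="negative"),
            ],
        ),
        record(  # no blood pressure after 20 weeks: not screened
            "P4",
            [
                _bp("P4", 10, 110, 70),
                _bp("P4", 22, None, None),
                _bp("P4", 26, None, None),
                _bp("P4", 30, None, None),
            ],
        ),
        record(  # hypertensive after 20 wk but never proteinuria-tested
            "P5",
            [
                _bp("P5", 10, 112, 72),
                _bp("P5", 22, 145, 92),
                _bp("P5", 26, 146, 92),
                _bp("P5", 30, 145, 93),
            ],
        ),
    ]
    for pid in ("P6", "P7", "P8"):
        recs.append(
            record(pid, [_bp(pid, 10, 110, 70), _bp(pid, 22, 112, 71), _bp(pid, 30, 109, 72)])
        )
    return cohort(recs)


@pytest.fixture
def iron_folate_fixture() -> Cohort:
    """8 pregnancies, eRegistry dialect: 3 anemic (1 untreated), 5 non-anemic
    (2 without routine supplementation) -> pooled correct supplementation 5/8."""
    recs = []
    spec = [
        ("A1", 9.5, "treatment"),
        ("A2", 9.8, "treatment"),
        ("A3", 9.2, "none"),
        ("B1", 12.5, "routine"),
        ("B2", 13.0, "routine"),
        ("B3", 12.1, "routine"),
        ("B4", 12.8, "none"),
        ("B5", 13.2, "none"),
    ]
    for pid, hb, iron in spec:
        recs.append(record(pid, [visit(pid, 12, hemoglobin=hb, iron_folate=iron)]))
    return cohort(recs)
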