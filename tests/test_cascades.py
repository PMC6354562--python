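"""Cascade indicators: hand-enumerated fixtures, limits, invariants."""
from __future__ import annotations

import dataclasses
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anclives import (
    ClinicalThresholds,
    CohortParams,
    apply_referral_censoring,
    degrade_to_dialect,
    diabetes_cascade,
    generate_cohort,
    health_status_indicators,
    hypertension_cascade,
    indicator_set,
    iron_folate_coverage,
    preeclampsia_cascade,
    tetanus_coverage,
)
from conftest import cohort, record, visit


def test_diabetes_fixture_hand_enumeration(diabetes_fixture):
    r = diabetes_cascade(diabetes_fixture)
    assert (r.eligible_n, r.screened_correctly_n, r.positive_n, r.correctly_managed_n) == (
        12,
        11,
        2,
        1,
    )
    assert r.coverage == pytest.approx(11 / 24)
    assert not r.undefined


def test_hypertension_fixture_hand_enumeration(hypertension_fixture):
    r = hypertension_cascade(hypertension_fixture)
    assert (r.eligible_n, r.screened_correctly_n, r.positive_n, r.correctly_managed_n) == (
        10,
        9,
        3,
        2,
    )
    assert r.coverage == pytest.approx(0.6)


def test_preeclampsia_fixture_hand_enumeration(preeclampsia_fixture):
    r = preeclampsia_cascade(preeclampsia_fixture)
    assert (r.eligible_n, r.screened_correctly_n, r.positive_n, r.correctly_managed_n) == (
        8,
        6,
        2,
        1,
    )
    assert r.coverage == pytest.approx(0.375)


def test_zero_screening_null_limit():
    params = CohortParams(
        n_pregnancies=500,
        seed=2,
        screening_compliance={"diabetes": 0.0, "hypertension": 0.0, "preeclampsia": 0.0},
    )
    r = diabetes_cascade(generate_cohort(params))
    assert r.positive_n == 0
    assert r.coverage == 0.0
    assert r.undefined  # no detected cases: composite has no denominator


def test_full_compliance_limit(full_compliance_params):
    c = apply_referral_censoring(generate_cohort(full_compliance_params))
    iset = indicator_set(c)
    for name, value in iset.coverage.items():
        assert value == 1.0, name


def test_no_hypertensives_flagged_undefined():
    recs = [
        record(p, [visit(p, 10, systolic_bp=110, diastolic_bp=70),
                   visit(p, 26, systolic_bp=112, diastolic_bp=72)])
        for p in ("N1", "N2")
    ]
    r = preeclampsia_cascade(cohort(recs))
    assert r.positive_n == 0
    assert r.undefined
    assert r.coverage == 0.0


def test_one_visit_missing_bp_fails_serial_screening():
    """Blood pressure is required at *every* attended visit."""
    recs = [
        record(
            p,
            [
                visit(p, 10, systolic_bp=110, diastolic_bp=70),
                visit(p, 26),  # no BP
            ],
        )
        for p in ("M1", "M2", "M3")
    ]
    r = hypertension_cascade(cohort(recs))
    assert r.screened_correctly_n == 0
    assert r.coverage == 0.0


class TestTetanus:
    def test_all_immune_full_documentation(self):
        recs = [
            record(p, [visit(p, 10, tetanus_entry_status="immune")]) for p in ("T1", "T2")
        ]
        assert tetanus_coverage(cohort(recs), "eregistry") == 1.0

    def test_all_missing_conservative_zero(self):
        recs = [record(p, [visit(p, 10)]) for p in ("T1", "T2")]
        for dialect in ("paper", "eregistry"):
            assert tetanus_coverage(cohort(recs), dialect) == 0.0

    def test_binomial_composition_of_compliance_and_missingness(self):
        """Guideline compliance 0.9 with 7% record-level missingness composes to
        0.9 x 0.93 observable coverage under the conservative rule."""
        params = CohortParams(
            n_pregnancies=10_000,
            seed=31,
            tetanus_immune_at_entry_prob=0.0,
            management_compliance={"tetanus": 0.9},
            missingness={"tetanus": 0.07},
        )
        c = generate_cohort(params)
        expected = 0.9 * 0.93
        se = math.sqrt(expected * (1 - expected) / len(c))
        for dialect in ("eregistry",):
            assert abs(tetanus_coverage(c, dialect) - expected) <= 3 * se


class TestIronFolate:
    def test_paper_checkbox_everyone(self):
        recs = [record(p, [visit(p, 10, iron_folate=True)]) for p in ("I1", "I2")]
        assert iron_folate_coverage(cohort(recs, dialect="paper"), "paper") == 1.0

    def test_eregistry_all_correctly_supplemented(self):
        recs = [
            record("I1", [visit("I1", 10, hemoglobin=9.0, iron_folate="treatment")]),
            record("I2", [visit("I2", 10, hemoglobin=12.5, iron_folate="routine")]),
        ]
        assert iron_folate_coverage(cohort(recs), "eregistry") == 1.0

    def test_pooled_fixture_direct_count(self, iron_folate_fixture):
        assert iron_folate_coverage(iron_folate_fixture, "eregistry") == pytest.approx(5 / 8)


class TestHealthStatus:
    def test_no_anemia_when_all_hemoglobin_high(self):
        recs = [record(p, [visit(p, 10, hemoglobin=12.5, bmi=23.0)]) for p in ("A1", "A2")]
        hs = health_status_indicators(cohort(recs))
        assert hs["anemia"] == 0.0 and hs["severe_anemia"] == 0.0

    def test_any_point_rule(self):
        recs = [
            record("A1", [visit("A1", 10, hemoglobin=10.2), visit("A1", 26, hemoglobin=11.4)])
        ] + [record(f"B{i}", [visit(f"B{i}", 10, hemoglobin=12.0)]) for i in range(9)]
        assert health_status_indicators(cohort(recs))["anemia"] == pytest.approx(0.1)

    def test_strict_cut_convention(self):
        values = [6.8, 10.9, 11.0, 13.0]
        recs = [
            record(f"C{i}", [visit(f"C{i}", 10, hemoglobin=hb)]) for i, hb in enumerate(values)
        ]
        hs = health_status_indicators(cohort(recs))
        assert hs["anemia"] == pytest.approx(2 / 4)  # 11.0 is not below 11
        assert hs["severe_anemia"] == pytest.approx(1 / 4)

    def test_low_bmi_at_booking_only(self):
        recs = [
            record("L1", [visit("L1", 10, bmi=17.5), visit("L1", 26, bmi=19.0)]),
            record("L2", [visit("L2", 10, bmi=22.0)]),
        ]
        assert health_status_indicators(cohort(recs))["low_bmi"] == pytest.approx(0.5)


@st.composite
def cohort_params(draw):
    htn = [
        draw(st.floats(0.0, 0.08)),
        draw(st.floats(0.0, 0.08)),
        draw(st.floats(0.0, 0.08)),
    ]
    comp = lambda: draw(st.floats(0.0, 1.0))
    return CohortParams(
        n_pregnancies=draw(st.integers(5, 60)),
        seed=draw(st.integers(0, 2**20)),
        incidence_diabetes=draw(st.floats(0.0, 0.3)),
        incidence_chronic_htn=htn[0],
        incidence_gest_htn_mild=htn[1],
        incidence_gest_htn_modsev=htn[2],
        incidence_preeclampsia=draw(st.floats(0.0, 1.0)) * sum(htn),
        screening_compliance={"diabetes": comp(), "hypertension": comp(), "preeclampsia": comp()},
        management_compliance={
            "diabetes": comp(),
            "hypertension": comp(),
            "preeclampsia": comp(),
            "tetanus": comp(),
        },
        iron_folate_given_prob=comp(),
        tetanus_immune_at_entry_prob=comp(),
        missingness={
            "tetanus": draw(st.floats(0.0, 0.6)),
            "tetanus_paper": draw(st.floats(0.0, 0.9)),
            "hemoglobin": draw(st.floats(0.0, 0.4)),
            "blood_pressure": draw(st.floats(0.0, 0.4)),
        },
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(params=cohort_params(), dialect=st.sampled_from(["paper", "eregistry"]))
def test_cascade_monotonicity_and_bounds_property(params, dialect):
    """eligible >= screened >= positive >= managed and all proportions in [0, 1]
    on arbitrary generator configurations, in both dialects, censored or not."""
    c = apply_referral_censoring(degrade_to_dialect(generate_cohort(params), dialect))
    iset = indicator_set(c)
    for cascade in iset.cascades.values():
        assert (
            cascade.eligible_n
            >= cascade.screened_correctly_n
            >= cascade.positive_n
            >= cascade.correctly_managed_n
            >= 0
        )
    for value in list(iset.coverage.values()) + list(iset.health_status.values()):
        assert 0.0 <= value <= 1.0
    assert iset.health_status["severe_anemia"] <= iset.health_status["anemia"]


def test_latent_truth_provably_unused():
    """Deleting or shuffling latent-truth annotations changes no indicator."""
    c = apply_referral_censoring(generate_cohort(CohortParams(n_pregnancies=400, seed=6)))
    baseline = indicator_set(c)

    stripped = dataclasses.replace(c)
    stripped.records = [dataclasses.replace(r, latent_truth=None) for r in c.records]
    shuffled = dataclasses.replace(c)
    truths = [r.latent_truth for r in c.records]
    random.Random(0).shuffle(truths)
    shuffled.records = [
        dataclasses.replace(r, latent_truth=t) for r, t in zip(c.records, truths)
    ]
    for variant in (stripped, shuffled):
        other = indicator_set(variant)
        assert other.coverage == baseline.coverage
        assert other.health_status == baseline.health_status


def test_indicator_set_equals_componentwise_results(diabetes_fixture):
    iset = indicator_set(diabetes_fixture)
    assert iset.coverage["diabetes_mgmt"] == diabetes_cascade(diabetes_fixture).coverage
    assert iset.coverage["htn_mgmt"] == hypertension_cascade(diabetes_fixture).coverage
    assert iset.coverage["tetanus"] == tetanus_coverage(diabetes_fixture, "eregistry")
    assert iset.health_status == health_status_indicators(diabetes_fixture)


def test_thresholds_validation():
    with pytest.raises(Exception, match="severe_anemia_cut"):
        ClinicalThresholds(anemia_cut=7.0, severe_anemia_cut=8.0)
    with pytest.raises(Exception, match="blood_sugar_window"):
        ClinicalThresholds(blood_sugar_window=(28, 24))
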