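"""Lives-saved engine: mixture arithmetic, calibration identity, brute-force
oracle equivalence, attribution and monotonicity."""
from __future__ import annotations

import math
import random

import pytest

from anclives import (
    ConfigurationError,
    EpiInputs,
    IndicatorSet,
    ScenarioSpec,
    build_scenarios,
    calibrate_envelope,
    compare,
    national_coverage,
    project_outcomes,
)
from anclives.projection import YEARS

INTERVENTIONS = ("diabetes_mgmt", "htn_mgmt", "preeclampsia_mgmt", "tetanus", "iron_folate")


def simple_epi(**overrides) -> EpiInputs:
    kw = dict(
        pregnancies_per_year=100_000.0,
        live_births_per_year=95_000.0,
        maternal_deaths_by_cause={"htn_cause": 30.0, "other_cause": 25.0},
        neonatal_deaths_by_cause={"tet_cause": 8.0, "neo_other": 1000.0},
        stillbirths_by_cause={"sb_cause": 700.0},
        anemia_prevalence_baseline=0.3,
        effectiveness={
            ("preeclampsia_mgmt", "htn_cause"): 0.6,
            ("htn_mgmt", "htn_cause"): 0.4,
            ("preeclampsia_mgmt", "sb_cause"): 0.45,
            ("diabetes_mgmt", "sb_cause"): 0.1,
            ("tetanus", "tet_cause"): 0.94,
            ("iron_folate", "anemia"): 0.67,
        },
        affected_fraction={
            ("preeclampsia_mgmt", "htn_cause"): 0.6,
            ("htn_mgmt", "htn_cause"): 0.4,
            ("preeclampsia_mgmt", "sb_cause"): 0.3,
            ("diabetes_mgmt", "sb_cause"): 0.25,
            ("tetanus", "tet_cause"): 1.0,
            ("iron_folate", "anemia"): 1.0,
        },
    )
    kw.update(overrides)
    return EpiInputs(**kw)


def flat_scenario(label: str, cov: dict[str, float], scale: dict[str, float] | None = None):
    coverage = {}
    for name, base in cov.items():
        if scale and name in scale:
            coverage[name] = (base,) + (scale[name],) * (len(YEARS) - 1)
        else:
            coverage[name] = (base,) * len(YEARS)
    return ScenarioSpec(label=label, coverage=coverage)


def indicator_set_for(coverage: dict[str, float | None]) -> IndicatorSet:
    availability = {
        k: ("direct" if coverage.get(k) is not None else "unavailable") for k in INTERVENTIONS
    }
    return IndicatorSet(
        source_dialect="eregistry",
        year=2017,
        coverage=dict(coverage),
        health_status={},
        availability=availability,
    )


class TestNationalCoverage:
    @pytest.mark.parametrize(
        "public, other, p_public, expected",
        [(0.9, 0.9, 0.3, 0.9), (0.9, 0.2, 1.0, 0.9), (0.9, 0.2, 0.6, 0.62)],
    )
    def test_mixture(self, public, other, p_public, expected):
        assert national_coverage(public, other, p_public) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ConfigurationError, match="p_public"):
            national_coverage(0.5, 0.5, 1.2)


class TestBuildScenarios:
    def test_noop_when_baseline_at_target(self):
        iset = indicator_set_for({k: 0.9 for k in INTERVENTIONS})
        comp, scale = build_scenarios(iset, p_public=0.6, target_public=0.9)
        assert comp.coverage == scale.coverage

    def test_mixture_arithmetic(self):
        iset = indicator_set_for({"tetanus": 0.35, **{k: None for k in INTERVENTIONS if k != "tetanus"}})
        comp, scale = build_scenarios(iset, p_public=0.6, target_public=0.9)
        assert comp.coverage["tetanus"] == (pytest.approx(0.35),) * 9
        assert scale.coverage["tetanus"][0] == pytest.approx(0.35)
        # 0.6 * 0.9 + 0.4 * 0.35 = 0.68 from 2018 onward
        assert scale.coverage["tetanus"][1:] == (pytest.approx(0.68),) * 8

    def test_unavailable_indicator_identical_and_flagged(self):
        iset = indicator_set_for({"tetanus": 0.35, **{k: None for k in INTERVENTIONS if k != "tetanus"}})
        comp, scale = build_scenarios(iset, p_public=0.6)
        for name in INTERVENTIONS:
            if name == "tetanus":
                continue
            assert name in comp.unavailable and name in scale.unavailable
            assert comp.coverage[name] == scale.coverage[name]

    def test_never_scales_down(self):
        iset = indicator_set_for({"tetanus": 0.95, **{k: None for k in INTERVENTIONS if k != "tetanus"}})
        comp, scale = build_scenarios(iset, p_public=0.6, target_public=0.9)
        assert scale.coverage["tetanus"] == comp.coverage["tetanus"]


class TestCalibration:
    def test_zero_coverage_identity(self):
        epi = simple_epi()
        env = calibrate_envelope(epi, {k: 0.0 for k in INTERVENTIONS})
        assert env.deaths["maternal"]["htn_cause"] == pytest.approx(30.0)
        assert env.anemia_p_star == pytest.approx(0.3)

    def test_single_intervention_closed_form(self):
        epi = simple_epi(
            effectiveness={("tetanus", "tet_cause"): 1.0},
            affected_fraction={("tetanus", "tet_cause"): 0.5},
        )
        env = calibrate_envelope(epi, {"tetanus": 0.5})
        # D* = D / (1 - 0.5 * 0.5) = D / 0.75
        assert env.deaths["neonatal"]["tet_cause"] == pytest.approx(8.0 / 0.75)

    def test_roundtrip_reproduces_envelope(self):
        epi = simple_epi()
        base = {k: v for k, v in zip(INTERVENTIONS, (0.2, 0.35, 0.15, 0.8, 0.6))}
        scenario = flat_scenario("steady", base)
        proj = project_outcomes(scenario, epi)
        assert proj.deaths["maternal"][2017] == pytest.approx(55.0, abs=1e-10)
        assert proj.deaths["neonatal"][2017] == pytest.approx(1008.0, abs=1e-10)
        assert proj.deaths["stillbirth"][2017] == pytest.approx(700.0, abs=1e-10)
        assert proj.anemia_prevalence[2017] == pytest.approx(0.3, abs=1e-12)

    def test_infeasible_parameters_rejected(self):
        epi = simple_epi(
            effectiveness={("tetanus", "tet_cause"): 1.0},
            affected_fraction={("tetanus", "tet_cause"): 1.0},
        )
        with pytest.raises(ConfigurationError, match="infeasible"):
            calibrate_envelope(epi, {"tetanus": 1.0})


class TestProjection:
    def test_constant_coverage_constant_deaths(self):
        proj = project_outcomes(flat_scenario("s", {"tetanus": 0.5}), simple_epi())
        values = list(proj.deaths["neonatal"].values())
        assert all(v == pytest.approx(values[0], abs=1e-12) for v in values)

    def test_elimination_limit(self):
        epi = simple_epi(
            neonatal_deaths_by_cause={"tet_cause": 8.0},
            effectiveness={("tetanus", "tet_cause"): 1.0},
            affected_fraction={("tetanus", "tet_cause"): 1.0},
        )
        scenario = flat_scenario("elim", {"tetanus": 0.0}, scale={"tetanus": 1.0})
        proj = project_outcomes(scenario, epi)
        assert proj.deaths["neonatal"][2025] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Engine equals an independently coded per-cause product evaluation to
        1e-10 on 100 random instances with up to 3 causes and 4 interventions."""
        rng = random.Random(12345)
        for trial in range(100):
            n_causes = rng.randint(1, 3)
            n_int = rng.randint(1, 4)
            interventions = [f"i{k}" for k in range(n_int)]
            causes = [f"c{k}" for k in range(n_causes)]
            eff = {(i, c): rng.uniform(0, 1) for i in interventions for c in causes}
            af = {(i, c): rng.uniform(0, 1) for i in interventions for c in causes}
            deaths = {c: rng.uniform(1, 500) for c in causes}
            epi = EpiInputs(
                pregnancies_per_year=50_000.0,
                live_births_per_year=48_000.0,
                maternal_deaths_by_cause=deaths,
                neonatal_deaths_by_cause={},
                stillbirths_by_cause={},
                anemia_prevalence_baseline=rng.uniform(0.05, 0.6),
                effectiveness=eff,
                affected_fraction=af,
            )
            base = {i: rng.uniform(0, 0.9) for i in interventions}
            target = {i: rng.uniform(base[i], 1.0) for i in interventions}
            scenario = flat_scenario("t", base, scale=target)
            proj = project_outcomes(scenario, epi)

            # --- independent brute force: plain-float loops, no engine code ---
            for year_idx, year in enumerate(YEARS):
                for c in causes:
                    denom = 1.0
                    for i in interventions:
                        denom *= 1.0 - eff[(i, c)] * af[(i, c)] * base[i]
                    d_star = deaths[c] / denom
                    expected = d_star
                    covs = base if year_idx == 0 else target
                    num = 1.0
                    for i in interventions:
                        num *= 1.0 - eff[(i, c)] * af[(i, c)] * covs[i]
                    expected = d_star * num
                    got = proj.deaths_by_cause["maternal"][c][year]
                    assert math.isclose(got, expected, rel_tol=0, abs_tol=1e-10), (
                        trial,
                        c,
                        year,
                    )


class TestCompare:
    def test_identical_scenarios_zero_averted(self):
        epi = simple_epi()
        base = {k: 0.3 for k in INTERVENTIONS}
        comp = flat_scenario("a", base)
        same = flat_scenario("b", base)
        summary = compare(comp, same, epi)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in summary.averted.values())
        assert all(a is None for a in summary.attribution.values())

    def test_single_delta_full_share(self):
        epi = simple_epi()
        base = {k: 0.3 for k in INTERVENTIONS}
        comp = flat_scenario("a", base)
        scale = flat_scenario("b", base, scale={"tetanus": 0.9})
        summary = compare(comp, scale, epi)
        assert summary.averted["neonatal"] > 0
        assert summary.attribution["neonatal"]["tetanus"] == pytest.approx(1.0)
        assert summary.averted["maternal"] == pytest.approx(0.0, abs=1e-12)

    def test_shares_sum_to_one_and_bounded(self):
        epi = simple_epi()
        base = {k: 0.2 for k in INTERVENTIONS}
        scale = {k: 0.9 for k in INTERVENTIONS}
        summary = compare(
            flat_scenario("a", base), flat_scenario("b", base, scale=scale), epi
        )
        for outcome, attr in summary.attribution.items():
            if attr is None:
                continue
            assert sum(attr.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0.0 <= share <= 1.0 for share in attr.values())

    def test_averted_nondecreasing_in_target(self):
        epi = simple_epi()
        iset = indicator_set_for(
            {"diabetes_mgmt": 0.1, "htn_mgmt": 0.2, "preeclampsia_mgmt": 0.15,
             "tetanus": 0.4, "iron_folate": 0.3}
        )
        previous = {o: -1.0 for o in ("maternal", "neonatal", "stillbirth", "anemia_cases")}
        for target in [0.5, 0.6, 0.7, 0.8, 0.9, 0.95]:
            comp, scale = build_scenarios(iset, p_public=0.6, target_public=target)
            summary = compare(comp, scale, epi)
            for outcome, value in summary.averted.items():
                assert value >= previous[outcome] - 1e-9, (outcome, target)
                previous[outcome] = value

    def test_rate_scales(self):
        epi = simple_epi()
        base = {k: 0.3 for k in INTERVENTIONS}
        summary = compare(
            flat_scenario("a", base), flat_scenario("b", base, scale={"tetanus": 0.9}), epi
        )
        r = summary.rates["comparator_2017"]
        proj = project_outcomes(flat_scenario("a", base), epi)
        assert r["mmr"] == pytest.approx(proj.deaths["maternal"][2017] / 95_000 * 1e5)
        assert r["nmr"] == pytest.approx(proj.deaths["neonatal"][2017] / 95_000 * 1e3)
        sb = proj.deaths["stillbirth"][2017]
        assert r["sbr"] == pytest.approx(sb / (95_000 + sb) * 1e3)
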