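"""Simplified deterministic lives-saved projection engine.

The engine follows the standard structure of deterministic lives-saved models:
each cause of death carries a latent no-intervention envelope D*, and observed
deaths under a coverage vector are

    deaths(c, t) = D*_c × Π_i (1 − Eff_{i,c} · AF_{i,c} · cov_{i,t})

with effectiveness Eff (relative risk reduction among affected cases), affected
fraction AF (share of the cause's deaths the intervention can act on) and
residual risks combined multiplicatively across interventions. D* is calibrated
so that projecting at baseline coverage exactly reproduces the supplied death
envelope. Anemia prevalence is handled analogously with a single latent
prevalence p* acted on by iron-folate supplementation.

Two national scenarios are compared: a steady state holding the 2017 baseline
through 2025, and a scale-up where public-sector coverage rises to a target
(default 90%) in 2018 and stays there, with other-sector coverage and the
public-sector share of attendance unchanged. The population is constant across
years; both scenarios share it, so between-scenario differences are unaffected.

The shipped default effectiveness / affected-fraction values in configs are
illustrative placeholders and clearly labeled as such; analyses set them
explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cascades import IndicatorSet
from .names import COVERAGE_INDICATORS, ConfigurationError

YEARS = tuple(range(2017, 2026))
DELTA_YEARS = tuple(range(2018, 2026))


def national_coverage(public_cov: float, other_cov: float, p_public: float) -> float:
    """Population mixture of sector coverages: p·public + (1−p)·other."""
    for name, v in (("public_cov", public_cov), ("other_cov", other_cov), ("p_public", p_public)):
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
    return p_public * public_cov + (1.0 - p_public) * other_cov


@dataclass
class ScenarioSpec:
    """Per-intervention national coverage trajectories over 2017–2025."""

    label: str
    coverage: dict[str, tuple[float, ...]]  # intervention -> one value per YEARS
    unavailable: frozenset[str] = frozenset()  # held-at-baseline, structurally zero delta

    def __post_init__(self) -> None:
        for name, traj in self.coverage.items():
            if len(traj) != len(YEARS):
                raise ConfigurationError(
                    f"{self.label}: trajectory for {name!r} must have "
                    f"{len(YEARS)} values, got {len(traj)}"
                )
            if any(not (0.0 <= v <= 1.0) for v in traj):
                raise ConfigurationError(
                    f"{self.label}: coverage for {name!r} outside [0, 1]: {traj}"
                )
            if len(set(traj[1:])) > 1:
                raise ConfigurationError(
                    f"{self.label}: coverage for {name!r} must be constant from 2018 on"
                )


@dataclass(frozen=True)
class EpiInputs:
    """Demographic and epidemiological scenario inputs (user-supplied envelopes).

    ``effectiveness`` and ``affected_fraction`` are keyed by (intervention, cause);
    causes are the keys of the per-outcome death maps. Mortality envelopes are
    per-year counts held constant across the projection window.
    """

    pregnancies_per_year: float
    live_births_per_year: float
    maternal_deaths_by_cause: Mapping[str, float]
    neonatal_deaths_by_cause: Mapping[str, float]
    stillbirths_by_cause: Mapping[str, float]
    anemia_prevalence_baseline: float
    effectiveness: Mapping[tuple[str, str], float]
    affected_fraction: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.pregnancies_per_year < 0 or self.live_births_per_year <= 0:
            raise ConfigurationError(
                "pregnancies_per_year must be >= 0 and live_births_per_year > 0"
            )
        for name in ("maternal_deaths_by_cause", "neonatal_deaths_by_cause", "stillbirths_by_cause"):
            for cause, count in getattr(self, name).items():
                if count < 0:
                    raise ConfigurationError(f"{name}[{cause!r}] must be >= 0")
        if not (0.0 <= self.anemia_prevalence_baseline <= 1.0):
            raise ConfigurationError("anemia_prevalence_baseline must be in [0, 1]")
        for name in ("effectiveness", "affected_fraction"):
            for key, v in getattr(self, name).items():
                if not (0.0 <= v <= 1.0):
                    raise ConfigurationError(f"{name}[{key!r}] must be in [0, 1], got {v}")

    def outcome_causes(self) -> dict[str, Mapping[str, float]]:
        return {
            "maternal": self.maternal_deaths_by_cause,
            "neonatal": self.neonatal_deaths_by_cause,
            "stillbirth": self.stillbirths_by_cause,
        }

    def impact(self, intervention: str, cause: str) -> float:
        return self.effectiveness.get((intervention, cause), 0.0) * self.affected_fraction.get(
            (intervention, cause), 0.0
        )


def build_scenarios(
    baseline: IndicatorSet,
    p_public: float,
    target_public: float = 0.9,
    other_cov_policy: str = "equal_to_public",
) -> tuple[ScenarioSpec, ScenarioSpec]:
    """Comparator (steady state) and scale-up scenario pair from one source.

    The baseline indicator value is the public-sector coverage observed in the
    source; other-sector coverage is imputed by policy (default: equal to the
    public baseline, i.e. quality of care constant across sectors), so the 2017
    national value equals the baseline. From 2018 the scale-up scenario replaces
    the public component with ``max(target_public, baseline)`` — coverage is
    never scaled down. Indicators the source cannot populate are held identical
    in both scenarios (structural zero delta) and flagged.
    """
    if not (0.0 <= p_public <= 1.0):
        raise ConfigurationError(f"p_public must be in [0, 1], got {p_public!r}")
    if not (0.0 <= target_public <= 1.0):
        raise ConfigurationError(f"target_public must be in [0, 1], got {target_public!r}")
    if other_cov_policy != "equal_to_public":
        raise ConfigurationError(f"unknown other_cov_policy {other_cov_policy!r}")

    comparator: dict[str, tuple[float, ...]] = {}
    scaled: dict[str, tuple[float, ...]] = {}
    unavailable = set()
    for name in COVERAGE_INDICATORS:
        value = baseline.coverage.get(name)
        if value is None or baseline.availability.get(name) == "unavailable":
            unavailable.add(name)
            comparator[name] = (0.0,) * len(YEARS)
            scaled[name] = (0.0,) * len(YEARS)
            continue
        other = value  # equal_to_public policy
        base_national = national_coverage(value, other, p_public)
        target_national = national_coverage(max(target_public, value), other, p_public)
        comparator[name] = (base_national,) * len(YEARS)
        scaled[name] = (base_national,) + (target_national,) * (len(YEARS) - 1)
    return (
        ScenarioSpec(label="steady_state", coverage=comparator, unavailable=frozenset(unavailable)),
        ScenarioSpec(label="scale_up_90", coverage=scaled, unavailable=frozenset(unavailable)),
    )


@dataclass(frozen=True)
class LatentEnvelope:
    """Zero-coverage death envelopes per outcome/cause plus latent anemia prevalence."""

    deaths: Mapping[str, Mapping[str, float]]  # outcome -> cause -> D*
    anemia_p_star: float


def calibrate_envelope(epi: EpiInputs, baseline_cov: Mapping[str, float]) -> LatentEnvelope:
    """Back out latent envelopes so projection at baseline coverage reproduces
    the observed ones: D*_c = D_c / Π_i (1 − Eff·AF·cov_i)."""
    deaths: dict[str, dict[str, float]] = {}
    for outcome, by_cause in epi.outcome_causes().items():
        deaths[outcome] = {}
        for cause, observed in by_cause.items():
            residual = 1.0
            for intervention, cov in baseline_cov.items():
                residual *= 1.0 - epi.impact(intervention, cause) * cov
            if residual <= 0.0:
                raise ConfigurationError(
                    f"infeasible parameters for cause {cause!r}: residual risk "
                    f"factor {residual} is not positive at baseline coverage"
                )
            deaths[outcome][cause] = observed / residual
    residual = 1.0 - epi.impact("iron_folate", "anemia") * baseline_cov.get("iron_folate", 0.0)
    if residual <= 0.0:
        raise ConfigurationError("infeasible iron-folate parameters for anemia")
    return LatentEnvelope(deaths=deaths, anemia_p_star=epi.anemia_prevalence_baseline / residual)


@dataclass
class ProjectionResult:
    """Deterministic per-year outcome counts for one scenario."""

    label: str
    deaths: dict[str, dict[int, float]]  # outcome -> year -> total deaths
    deaths_by_cause: dict[str, dict[str, dict[int, float]]]  # outcome -> cause -> year
    anemia_prevalence: dict[int, float]
    anemia_cases: dict[int, float]


def project_outcomes(scenario: ScenarioSpec, epi: EpiInputs) -> ProjectionResult:
    """Project yearly deaths and anemia cases for a scenario.

    The latent envelope is calibrated on the scenario's 2017 coverage (shared by
    construction between a comparator and its scale-up), so the 2017 projection
    reproduces the input envelope identically.
    """
    base_cov = {name: traj[0] for name, traj in scenario.coverage.items()}
    envelope = calibrate_envelope(epi, base_cov)

    deaths: dict[str, dict[int, float]] = {}
    by_cause: dict[str, dict[str, dict[int, float]]] = {}
    for outcome, causes in envelope.deaths.items():
        by_cause[outcome] = {cause: {} for cause in causes}
        deaths[outcome] = {}
        for t, year in enumerate(YEARS):
            total = 0.0
            for cause, d_star in causes.items():
                residual = 1.0
                for intervention, traj in scenario.coverage.items():
                    residual *= 1.0 - epi.impact(intervention, cause) * traj[t]
                value = d_star * residual
                by_cause[outcome][cause][year] = value
                total += value
            deaths[outcome][year] = total

    prevalence: dict[int, float] = {}
    cases: dict[int, float] = {}
    iron = scenario.coverage.get("iron_folate", (0.0,) * len(YEARS))
    for t, year in enumerate(YEARS):
        p = envelope.anemia_p_star * (1.0 - epi.impact("iron_folate", "anemia") * iron[t])
        prevalence[year] = p
        cases[year] = epi.pregnancies_per_year * p
    return ProjectionResult(
        label=scenario.label,
        deaths=deaths,
        deaths_by_cause=by_cause,
        anemia_prevalence=prevalence,
        anemia_cases=cases,
    )


@dataclass
class AvertedSummary:
    """Cumulative 2018–2025 differences between comparator and scale-up.

    ``attribution[outcome]`` maps each intervention to its share of the outcome's
    averted total, computed by scaling one intervention at a time (others held at
    comparator) and normalizing; ``None`` when nothing was averted. Rates are on
    the conventional scales: maternal mortality ratio per 100,000 live births,
    neonatal mortality and stillbirth rates per 1,000, anemia in percent.
    Percent changes are reported both against the scenario's own 2017 value and
    against the comparator's 2025 value.
    """

    averted: dict[str, float]
    attribution: dict[str, dict[str, float] | None]
    rates: dict[str, dict[str, float]]


def _cumulative(result: ProjectionResult, outcome: str) -> float:
    if outcome == "anemia_cases":
        return sum(result.anemia_cases[y] for y in DELTA_YEARS)
    return sum(result.deaths[outcome][y] for y in DELTA_YEARS)


def _rates(result: ProjectionResult, epi: EpiInputs, year: int) -> dict[str, float]:
    lb = epi.live_births_per_year
    sb = result.deaths["stillbirth"][year]
    return {
        "mmr": result.deaths["maternal"][year] / lb * 1e5,
        "nmr": result.deaths["neonatal"][year] / lb * 1e3,
        "sbr": sb / (lb + sb) * 1e3,
        "anemia_pct": result.anemia_prevalence[year] * 100.0,
    }


def compare(
    comparator: ScenarioSpec, intervention: ScenarioSpec, epi: EpiInputs
) -> AvertedSummary:
    """Averted outcomes, per-intervention attribution and rate changes.

    Attribution scales one intervention at a time: intervention i takes its
    scale-up trajectory while every other stays at the comparator's, and the
    resulting one-at-a-time averted totals are normalized to shares.
    """
    comp = project_outcomes(comparator, epi)
    full = project_outcomes(intervention, epi)

    outcomes = ("maternal", "neonatal", "stillbirth", "anemia_cases")
    averted = {o: _cumulative(comp, o) - _cumulative(full, o) for o in outcomes}

    one_at_a_time: dict[str, dict[str, float]] = {o: {} for o in outcomes}
    for name in intervention.coverage:
        if intervention.coverage[name] == comparator.coverage[name]:
            for o in outcomes:
                one_at_a_time[o][name] = 0.0
            continue
        solo_cov = dict(comparator.coverage)
        solo_cov[name] = intervention.coverage[name]
        solo = ScenarioSpec(
            label=f"solo_{name}", coverage=solo_cov, unavailable=comparator.unavailable
        )
        solo_result = project_outcomes(solo, epi)
        for o in outcomes:
            one_at_a_time[o][name] = _cumulative(comp, o) - _cumulative(solo_result, o)

    attribution: dict[str, dict[str, float] | None] = {}
    for o in outcomes:
        total = sum(one_at_a_time[o].values())
        if averted[o] <= 0.0 or total <= 0.0:
            attribution[o] = None
        else:
            attribution[o] = {k: v / total for k, v in one_at_a_time[o].items()}

    rates = {
        "comparator_2017": _rates(comp, epi, 2017),
        "comparator_2025": _rates(comp, epi, 2025),
        "intervention_2025": _rates(full, epi, 2025),
    }
    changes_own: dict[str, float] = {}
    changes_vs_comp: dict[str, float] = {}
    for key, v2017 in rates["comparator_2017"].items():
        v_int = rates["intervention_2025"][key]
        v_comp = rates["comparator_2025"][key]
        changes_own[key] = 100.0 * (v2017 - v_int) / v2017 if v2017 else 0.0
        changes_vs_comp[key] = 100.0 * (v_comp - v_int) / v_comp if v_comp else 0.0
    rates["pct_change_vs_2017"] = changes_own
    rates["pct_change_vs_comparator_2025"] = changes_vs_comp

    return AvertedSummary(averted=averted, attribution=attribution, rates=rates)
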