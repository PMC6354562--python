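"""Indicator estimation from aggregate sources, and per-source availability.

Routine reports give counts (cases referred, pregnancies registered) that need an
externally supplied incidence to become a management-coverage proportion — in the
study design, incidence is borrowed from the record-level paper cohort. Household
surveys give contact coverage only; an indirect effective-coverage estimator
(contact coverage times a facility-readiness/quality fraction, the crosswalk
family of estimators) fills the gap, as a pluggable strategy so a published
regression-based formula can be substituted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

from .names import (
    COVERAGE_INDICATORS,
    HEALTH_STATUS_INDICATORS,
    SOURCES,
    ConfigurationError,
    UndefinedIndicatorError,
)


class SaturationWarning(UserWarning):
    """A routine ratio exceeded 1: numerator and denominator come from different
    reporting levels and can over-report; the value is capped at 1.0."""


@dataclass(frozen=True)
class RoutineAggregates:
    referred_diabetes: int
    referred_preeclampsia: int
    pregnancies_registered: int
    incidence_diabetes: float
    incidence_preeclampsia: float
    p_public: float

    def __post_init__(self) -> None:
        for name in ("referred_diabetes", "referred_preeclampsia", "pregnancies_registered"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("incidence_diabetes", "incidence_preeclampsia", "p_public"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v!r}")
        if max(self.referred_diabetes, self.referred_preeclampsia) > self.pregnancies_registered:
            raise ConfigurationError(
                "referred counts cannot exceed pregnancies_registered"
            )


@dataclass(frozen=True)
class SurveyInputs:
    contact_coverage: float
    quality_fraction: float
    p_public_survey: float = 1.0

    def __post_init__(self) -> None:
        for name in ("contact_coverage", "quality_fraction", "p_public_survey"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")


def routine_management_coverage(referred: int, registered: int, incidence: float) -> float:
    """Cases referred / (pregnancies registered × incidence), capped at 1.

    A ratio above 1 signals over-reporting between reporting levels; it is capped
    with a :class:`SaturationWarning` rather than rejected.
    """
    if registered <= 0 or incidence <= 0:
        raise UndefinedIndicatorError(
            "routine management coverage undefined: registered pregnancies and "
            f"incidence must be positive (got registered={registered}, incidence={incidence})"
        )
    if referred < 0:
        raise ConfigurationError(f"referred count must be >= 0, got {referred}")
    ratio = referred / (registered * incidence)
    if ratio > 1.0:
        warnings.warn(
            f"routine indicator saturated: referred={referred} exceeds expected "
            f"cases {registered * incidence:.1f}; capping coverage at 1.0",
            SaturationWarning,
            stacklevel=2,
        )
        return 1.0
    return ratio


def indirect_effective_coverage(
    inputs: SurveyInputs,
    strategy: Callable[[SurveyInputs], float] | None = None,
) -> float:
    """Survey-based indirect estimate of effective coverage.

    The default strategy is the effective-coverage crosswalk, contact coverage ×
    quality fraction; pass ``strategy`` to substitute a published formula.
    Never exceeds contact coverage (the quality fraction is at most 1).
    """
    if strategy is not None:
        value = float(strategy(inputs))
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"indirect strategy returned {value}, outside [0, 1]")
        return value
    return inputs.contact_coverage * inputs.quality_fraction


_AVAILABILITY = {
    "routine": {
        "diabetes_mgmt": "direct",
        "htn_mgmt": "unavailable",
        "preeclampsia_mgmt": "direct",
        "tetanus": "unavailable",
        "iron_folate": "unavailable",
        "anemia": "unavailable",
        "severe_anemia": "unavailable",
        "low_bmi": "unavailable",
    },
    "mics": {
        "diabetes_mgmt": "indirect",
        "htn_mgmt": "indirect",
        "preeclampsia_mgmt": "indirect",
        "tetanus": "unavailable",
        "iron_folate": "unavailable",
        "anemia": "unavailable",
        "severe_anemia": "unavailable",
        "low_bmi": "unavailable",
    },
    "paper": {name: "direct" for name in COVERAGE_INDICATORS + HEALTH_STATUS_INDICATORS},
    "eregistry": {name: "direct" for name in COVERAGE_INDICATORS + HEALTH_STATUS_INDICATORS},
}


def available_indicators(source: str) -> dict[str, str]:
    """Which of the eight indicators a source can populate, and how.

    Routine reports populate 2 of 5 coverage indicators directly and no health
    status; the survey populates 3 of 5 indirectly and no health status; both
    record dialects populate all eight directly. Unavailable indicators are
    explicit markers, never zeros.
    """
    if source not in SOURCES:
        raise ConfigurationError(f"unknown source {source!r}; expected one of {SOURCES}")
    return dict(_AVAILABILITY[source])
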