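"""Shared vocabulary: indicator, source and dialect names used across modules."""

#: The five intervention-coverage indicators a full antenatal block needs.
COVERAGE_INDICATORS = (
    "diabetes_mgmt",
    "htn_mgmt",
    "preeclampsia_mgmt",
    "tetanus",
    "iron_folate",
)

#: The three health-status indicators (prevalences, not interventions).
HEALTH_STATUS_INDICATORS = ("anemia", "severe_anemia", "low_bmi")

#: Record-level data dialects (field availability / encoding conventions).
DIALECTS = ("paper", "eregistry")

#: The four data sources being compared.
SOURCES = ("routine", "mics", "paper", "eregistry")

#: Projection outcomes.
OUTCOMES = ("maternal", "neonatal", "stillbirth", "anemia_cases")


class ConfigurationError(ValueError):
    """A parameter or configuration block is invalid; the message names the field."""


class SchemaError(KeyError):
    """A tabular input lacks a required column; the message names it."""


class UndefinedIndicatorError(ZeroDivisionError):
    """An indicator's denominator is structurally zero (e.g. zero registered pregnancies)."""
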