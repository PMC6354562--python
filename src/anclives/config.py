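"""Run configuration: validated, YAML-loadable description of a full comparison.

A run names the data sources to compare (routine report aggregates, survey
inputs, and synthetic record-level cohorts in each dialect), the clinical
thresholds, the epidemiological scenario inputs for the projection engine, the
public-sector attendance share per source, and a single seed from which every
cohort's seed is derived.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cascades import ClinicalThresholds
from .cohort import CohortParams
from .names import SOURCES
from .projection import EpiInputs


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RoutineBlock(_Block):
    referred_diabetes: int = Field(ge=0)
    referred_preeclampsia: int = Field(ge=0)
    pregnancies_registered: int = Field(gt=0)
    # When omitted, incidence is borrowed from the paper-record cohort's cascades,
    # mirroring the study design (routine reports carry counts, not incidence).
    incidence_diabetes: Optional[float] = Field(default=None, gt=0, le=1)
    incidence_preeclampsia: Optional[float] = Field(default=None, gt=0, le=1)


class MicsBlock(_Block):
    contact_coverage: float = Field(ge=0, le=1)
    #: indicator -> facility readiness / quality fraction for the indirect estimator
    quality_fraction: dict[str, float]

    @model_validator(mode="after")
    def _check_quality(self) -> "MicsBlock":
        for name, v in self.quality_fraction.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"quality_fraction[{name!r}] must be in [0, 1], got {v}")
        return self


class CohortBlock(_Block):
    """Overrides applied on top of the CohortParams defaults."""

    model_config = ConfigDict(extra="allow")

    def build_params(self, seed: int) -> CohortParams:
        overrides = dict(self.model_dump(exclude_none=True))
        overrides["seed"] = seed
        return CohortParams.from_dict({**CohortParams().to_dict(), **overrides})


class SourcesBlock(_Block):
    routine: Optional[RoutineBlock] = None
    mics: Optional[MicsBlock] = None
    paper: Optional[CohortBlock] = None
    eregistry: Optional[CohortBlock] = None

    def configured(self) -> list[str]:
        return [s for s in SOURCES if getattr(self, s) is not None]


class EpiBlock(_Block):
    pregnancies_per_year: float = Field(ge=0)
    live_births_per_year: float = Field(gt=0)
    maternal_deaths_by_cause: dict[str, float]
    neonatal_deaths_by_cause: dict[str, float]
    stillbirths_by_cause: dict[str, float]
    anemia_prevalence_baseline: float = Field(ge=0, le=1)
    effectiveness: dict[str, dict[str, float]]
    affected_fraction: dict[str, dict[str, float]]

    def build_epi(self) -> EpiInputs:
        flat = lambda nested: {
            (intervention, cause): value
            for intervention, by_cause in nested.items()
            for cause, value in by_cause.items()
        }
        return EpiInputs(
            pregnancies_per_year=self.pregnancies_per_year,
            live_births_per_year=self.live_births_per_year,
            maternal_deaths_by_cause=dict(self.maternal_deaths_by_cause),
            neonatal_deaths_by_cause=dict(self.neonatal_deaths_by_cause),
            stillbirths_by_cause=dict(self.stillbirths_by_cause),
            anemia_prevalence_baseline=self.anemia_prevalence_baseline,
            effectiveness=flat(self.effectiveness),
            affected_fraction=flat(self.affected_fraction),
        )


class RunConfig(_Block):
    seed: int = 0
    out_dir: str = "results/run"
    log_level: str = "INFO"
    target_public: float = Field(default=0.9, ge=0, le=1)
    with_truth: bool = False
    p_public: dict[str, float]
    thresholds: dict = Field(default_factory=dict)
    epi: EpiBlock
    sources: SourcesBlock

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        configured = self.sources.configured()
        if not configured:
            raise ValueError("at least one source block must be configured under 'sources'")
        for source, v in self.p_public.items():
            if source not in SOURCES:
                raise ValueError(f"p_public names unknown source {source!r}")
            if not (0.0 < v <= 1.0):
                raise ValueError(f"p_public[{source!r}] must be in (0, 1], got {v}")
        missing = [s for s in configured if s not in self.p_public]
        if missing:
            raise ValueError(f"p_public missing for configured source(s): {missing}")
        return self

    def build_thresholds(self) -> ClinicalThresholds:
        overrides = dict(self.thresholds)
        if "blood_sugar_window" in overrides:
            overrides["blood_sugar_window"] = tuple(overrides["blood_sugar_window"])
        return ClinicalThresholds(**overrides)

    def cohort_seed(self, source: str) -> int:
        """Deterministic per-source cohort seed derived from the run seed."""
        offset = {"paper": 1, "eregistry": 2}[source]
        return (self.seed * 1_000_003 + offset) % 2**31


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(data)


def validate_config(config: dict | RunConfig) -> list[tuple[str, str]]:
    """Exhaustive validation with actionable messages.

    Returns (level, message) diagnostics: ``error`` entries name the offending
    field; ``warning`` entries flag saturated routine indicators (referred counts
    exceeding registered × incidence). An empty list means the configuration is
    clean.
    """
    diagnostics: list[tuple[str, str]] = []
    if isinstance(config, RunConfig):
        cfg = config
    else:
        try:
            cfg = RunConfig.model_validate(config)
        except ValidationError as exc:
            for err in exc.errors():
                loc = ".".join(str(p) for p in err["loc"])
                diagnostics.append(("error", f"{loc}: {err['msg']}"))
            return diagnostics
    routine = cfg.sources.routine
    if routine is not None:
        for label, referred, incidence in (
            ("diabetes", routine.referred_diabetes, routine.incidence_diabetes),
            ("preeclampsia", routine.referred_preeclampsia, routine.incidence_preeclampsia),
        ):
            if incidence is not None:
                expected = routine.pregnancies_registered * incidence
                if referred > expected:
                    diagnostics.append(
                        (
                            "warning",
                            f"routine {label} indicator saturated: referred "
                            f"({referred}) exceeds registered x incidence "
                            f"({expected:.1f}); coverage will be capped at 1.0",
                        )
                    )
    try:
        cfg.epi.build_epi()
    except Exception as exc:  # surfaced as a diagnostic, not a crash
        diagnostics.append(("error", f"epi: {exc}"))
    return diagnostics
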