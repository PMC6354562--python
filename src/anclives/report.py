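"""End-to-end orchestration: sources → indicator sets → scenarios → averted summary.

`run_comparison` reproduces the study design for every configured source: build
its indicator set (record-level cascades, routine ratios with borrowed incidence,
or survey-based indirect estimates), hold the 2017 national baseline flat as the
comparator, scale public-sector coverage to the target from 2018, project both
scenarios through the lives-saved engine and summarize deaths and anemia cases
averted with per-intervention attribution. Outputs are plain CSV/JSON/Markdown
and byte-identical under an identical configuration.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cascades import IndicatorSet, indicator_set
from .cohort import Cohort, apply_referral_censoring, degrade_to_dialect, generate_cohort, write_cohort_csv
from .config import RunConfig
from .names import (
    COVERAGE_INDICATORS,
    HEALTH_STATUS_INDICATORS,
    ConfigurationError,
)
from .projection import AvertedSummary, ScenarioSpec, build_scenarios, compare, project_outcomes
from .sources import (
    SurveyInputs,
    available_indicators,
    indirect_effective_coverage,
    routine_management_coverage,
)


@dataclass
class SourceResult:
    source: str
    indicators: IndicatorSet
    comparator: ScenarioSpec
    scale_up: ScenarioSpec
    summary: AvertedSummary


@dataclass
class ComparisonReport:
    sources: dict[str, SourceResult]
    manifest: dict

    def indicator_frame(self) -> pd.DataFrame:
        rows = []
        for source, res in self.sources.items():
            for name in COVERAGE_INDICATORS:
                value = res.indicators.coverage.get(name)
                rows.append(
                    {
                        "source": source,
                        "indicator": name,
                        "kind": "coverage",
                        "availability": res.indicators.availability.get(name, "unavailable"),
                        "value": value,
                        "national_baseline": res.comparator.coverage[name][0]
                        if name not in res.comparator.unavailable
                        else None,
                        "national_target": res.scale_up.coverage[name][-1]
                        if name not in res.scale_up.unavailable
                        else None,
                    }
                )
            for name in HEALTH_STATUS_INDICATORS:
                rows.append(
                    {
                        "source": source,
                        "indicator": name,
                        "kind": "health_status",
                        "availability": res.indicators.availability.get(name, "unavailable"),
                        "value": res.indicators.health_status.get(name),
                        "national_baseline": None,
                        "national_target": None,
                    }
                )
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        out: dict = {}
        for source, res in self.sources.items():
            out[source] = {
                "averted_2018_2025": res.summary.averted,
                "attribution": res.summary.attribution,
                "rates": res.summary.rates,
            }
        return out

    def comparison_markdown(self) -> str:
        """A comparison matrix shaped like the study's results table."""
        sources = list(self.sources)
        lines = ["# Cross-source comparison", ""]
        header = "| | " + " | ".join(sources) + " |"
        sep = "|---" * (len(sources) + 1) + "|"
        lines += [header, sep]

        def row(label: str, cells: list[str]) -> None:
            lines.append("| " + label + " | " + " | ".join(cells) + " |")

        pretty = {
            "maternal": "Maternal lives saved",
            "neonatal": "Newborn lives saved",
            "stillbirth": "Stillbirths averted",
            "anemia_cases": "Maternal anemia cases averted",
        }
        for outcome, label in pretty.items():
            row(
                label,
                [f"{self.sources[s].summary.averted[outcome]:.0f}" for s in sources],
            )
        for outcome, label in pretty.items():
            cells = []
            for s in sources:
                attr = self.sources[s].summary.attribution[outcome]
                if attr is None:
                    cells.append("-")
                else:
                    parts = [
                        f"{name} ({share * 100.0:.0f}%)"
                        for name, share in sorted(attr.items(), key=lambda kv: -kv[1])
                        if share > 0.005
                    ]
                    cells.append("; ".join(parts) if parts else "-")
            row(f"Interventions averting: {label.lower()}", cells)
        rate_labels = {
            "mmr": "MMR 2017/2025 (per 100,000)",
            "nmr": "NMR 2017/2025 (per 1,000)",
            "sbr": "SBR 2017/2025 (per 1,000)",
            "anemia_pct": "Anemia % 2017/2025",
        }
        for key, label in rate_labels.items():
            cells = []
            for s in sources:
                r = self.sources[s].summary.rates
                cells.append(
                    f"{r['comparator_2017'][key]:.0f}/{r['intervention_2025'][key]:.0f} "
                    f"({r['pct_change_vs_2017'][key]:.0f}%)"
                )
            row(label, cells)
        lines.append("")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "indicators": out / "indicators.csv",
            "summary": out / "summary.json",
            "comparison": out / "comparison.md",
            "manifest": out / "manifest.json",
        }
        self.indicator_frame().to_csv(paths["indicators"], index=False)
        paths["summary"].write_text(json.dumps(self.summary_dict(), indent=2, sort_keys=True))
        paths["comparison"].write_text(self.comparison_markdown())
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return paths


def _record_source_indicators(
    config: RunConfig, source: str, thresholds
) -> tuple[IndicatorSet, Cohort]:
    block = getattr(config.sources, source)
    params = block.build_params(seed=config.cohort_seed(source))
    cohort = generate_cohort(params)
    cohort = degrade_to_dialect(cohort, source)
    cohort = apply_referral_censoring(cohort)
    iset = indicator_set(cohort, source, thresholds)
    return iset, cohort


def _routine_indicators(config: RunConfig, paper_iset: IndicatorSet | None) -> IndicatorSet:
    block = config.sources.routine
    availability = available_indicators("routine")

    def borrowed(name: str, given: float | None) -> float:
        if given is not None:
            return given
        if paper_iset is None or name not in paper_iset.cascades:
            raise ConfigurationError(
                f"routine incidence for {name!r} not configured and no paper-record "
                "cohort is available to borrow it from"
            )
        cascade = paper_iset.cascades[name]
        if cascade.screened_correctly_n == 0:
            raise ConfigurationError(
                f"cannot borrow {name!r} incidence: paper cohort screened nobody"
            )
        return cascade.positive_n / cascade.screened_correctly_n

    inc_dia = borrowed("diabetes_mgmt", block.incidence_diabetes)
    inc_pe = borrowed("preeclampsia_mgmt", block.incidence_preeclampsia)
    coverage: dict[str, float | None] = {name: None for name in COVERAGE_INDICATORS}
    coverage["diabetes_mgmt"] = routine_management_coverage(
        block.referred_diabetes, block.pregnancies_registered, inc_dia
    )
    coverage["preeclampsia_mgmt"] = routine_management_coverage(
        block.referred_preeclampsia, block.pregnancies_registered, inc_pe
    )
    return IndicatorSet(
        source_dialect="routine",
        year=2016,
        coverage=coverage,
        health_status={name: None for name in HEALTH_STATUS_INDICATORS},
        availability=availability,
    )


def _mics_indicators(config: RunConfig) -> IndicatorSet:
    block = config.sources.mics
    availability = available_indicators("mics")
    coverage: dict[str, float | None] = {name: None for name in COVERAGE_INDICATORS}
    for name, avail in availability.items():
        if avail == "indirect" and name in COVERAGE_INDICATORS:
            quality = block.quality_fraction.get(name)
            if quality is None:
                raise ConfigurationError(
                    f"mics.quality_fraction missing entry for indirect indicator {name!r}"
                )
            coverage[name] = indirect_effective_coverage(
                SurveyInputs(
                    contact_coverage=block.contact_coverage,
                    quality_fraction=quality,
                    p_public_survey=config.p_public.get("mics", 1.0),
                )
            )
    return IndicatorSet(
        source_dialect="mics",
        year=2014,
        coverage=coverage,
        health_status={name: None for name in HEALTH_STATUS_INDICATORS},
        availability=availability,
    )


def run_comparison(config: RunConfig, write: bool = True, write_cohorts: bool = False) -> ComparisonReport:
    """Run the full multi-source comparison described by ``config``.

    Identical configurations produce byte-identical outputs: every random draw
    flows from ``config.seed`` through a documented per-source derivation, and
    all emitted files avoid timestamps and unordered containers.
    """
    thresholds = config.build_thresholds()
    epi_base = config.epi.build_epi()
    configured = config.sources.configured()

    record_sets: dict[str, IndicatorSet] = {}
    cohorts: dict[str, Cohort] = {}
    for source in ("paper", "eregistry"):
        if source in configured:
            record_sets[source], cohorts[source] = _record_source_indicators(
                config, source, thresholds
            )

    results: dict[str, SourceResult] = {}
    for source in configured:
        if source == "routine":
            iset = _routine_indicators(config, record_sets.get("paper"))
        elif source == "mics":
            iset = _mics_indicators(config)
        else:
            iset = record_sets[source]
        # Record-level sources measure anemia themselves; aggregate sources fall
        # back to the configured (model-default) prevalence.
        anemia = iset.health_status.get("anemia")
        epi_src = (
            dataclasses.replace(epi_base, anemia_prevalence_baseline=anemia)
            if anemia is not None
            else epi_base
        )
        comparator, scale_up = build_scenarios(
            iset, p_public=config.p_public[source], target_public=config.target_public
        )
        summary = compare(comparator, scale_up, epi_src)
        results[source] = SourceResult(
            source=source,
            indicators=iset,
            comparator=comparator,
            scale_up=scale_up,
            summary=summary,
        )

    manifest = {
        "package": "anclives",
        "version": __version__,
        "seed": config.seed,
        "cohort_seeds": {
            s: config.cohort_seed(s) for s in ("paper", "eregistry") if s in configured
        },
        "sources": configured,
        "target_public": config.target_public,
        # out_dir is a runtime location, not part of the scientific configuration
        "config": config.model_dump(mode="json", exclude={"out_dir"}),
    }
    report = ComparisonReport(sources=results, manifest=manifest)
    if write:
        paths = report.write(config.out_dir)
        if write_cohorts:
            for source, cohort in cohorts.items():
                write_cohort_csv(
                    cohort,
                    Path(config.out_dir) / f"cohort_{source}.csv",
                    with_truth=config.with_truth,
                )
    return report


def projection_frame(result_source: SourceResult, epi) -> pd.DataFrame:
    """Per-year projected outcomes for both scenarios of one source."""
    rows = []
    for scenario in (result_source.comparator, result_source.scale_up):
        proj = project_outcomes(scenario, epi)
        for outcome, by_year in proj.deaths.items():
            for year, value in by_year.items():
                rows.append(
                    {"scenario": scenario.label, "outcome": outcome, "year": year, "value": value}
                )
        for year, value in proj.anemia_cases.items():
            rows.append(
                {"scenario": scenario.label, "outcome": "anemia_cases", "year": year, "value": value}
            )
    return pd.DataFrame(rows)
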