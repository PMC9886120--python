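"""End-to-end analysis: load/generate → exclude → expose → score → associate.

The report mirrors a cross-sectional study write-up: cohort accounting
(including the eligibility filter's in/out counts), the weekly-exposure
summary, symptom prevalence tables, crude exposure–outcome associations,
and the sex-adjusted (Mantel–Haenszel) odds ratio for probable hearing
loss.  Every number in the report is produced by the library modules; this
layer only orchestrates and serializes.  Reports carry no timestamp, so a
fixed input (or fixed simulation seed) yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from importlib.metadata import PackageNotFoundError, version as _dist_version

from .catalog import Catalog, default_catalog
from .cohort import Cohort, Participant, apply_eligibility, read_cohort
from .exposure import exposure_summary
from .scoring import (
    PROBABLE_LOSS_CUTOFF,
    hearing_score,
    score_distribution,
    symptom_prevalence,
)
from .stats import TwoByTwo, associate, build_table, mantel_haenszel
from .simulate import SimulationConfig, generate_cohort

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "render_tables", "write_report"]

log = logging.getLogger("leisurenoise")

try:
    _pkg_version = _dist_version("leisurenoise")
except PackageNotFoundError:  # pragma: no cover - not installed
    _pkg_version = "0+unknown"


@dataclass(frozen=True)
class AnalysisConfig:
    threshold_dba: float = 85.0
    reference_hours: float = 40.0
    age_range: tuple[int, int] = (18, 29)
    ci_method: str = "wald"
    confidence: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)


@dataclass(frozen=True)
class AnalysisReport:
    """Machine-readable report plus the per-participant intermediate tables."""

    data: dict
    participant_exposures: pd.DataFrame
    participant_scores: pd.DataFrame

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True, **kwargs)


def _probable_loss(p: Participant) -> bool:
    return hearing_score(p.hearing_items).classification == "probable_hearing_loss"


def _association_row(
    cohort: Cohort, outcome_name: str, exposure_name: str, expose_fn, outcome_fn,
    confidence: float,
) -> dict:
    table = build_table(cohort, expose_fn, outcome_fn)
    res = associate(table, confidence)
    return {
        "outcome": outcome_name,
        "exposure": exposure_name,
        "a": table.a,
        "b": table.b,
        "c": table.c,
        "d": table.d,
        "odds_ratio": res.odds_ratio,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "chi2": res.chi2_statistic,
        "p_value": res.p_value,
        "zero_cell_corrected": res.zero_cell_corrected,
    }


def run_full_analysis(
    source: Union[str, Path, Cohort, SimulationConfig],
    config: AnalysisConfig | None = None,
    catalog: Catalog | None = None,
) -> AnalysisReport:
    """Run the whole pipeline on a survey file, a cohort, or a simulation config.

    Deterministic for a fixed input file or a fixed simulation seed.  All
    report sections are present even when the eligible cohort is empty.
    """
    config = config or AnalysisConfig()
    catalog = catalog if catalog is not None else default_catalog()

    log.info("stage load: start")
    if isinstance(source, SimulationConfig):
        cohort = generate_cohort(source, catalog)
    elif isinstance(source, Cohort):
        cohort = source
    else:
        cohort = read_cohort(source, catalog)
    log.info("stage load: %d participants", len(cohort))

    eligible, exclusions = apply_eligibility(cohort, config.age_range)
    log.info(
        "stage eligibility: %d in, %d excluded, %d retained",
        len(cohort), len(exclusions), len(eligible),
    )
    reason_counts: dict[str, int] = {}
    for e in exclusions:
        reason_counts[e.reason] = reason_counts.get(e.reason, 0) + 1

    n = len(eligible)
    exposures, summary = exposure_summary(
        eligible, config.reference_hours, config.threshold_dba
    )
    exp_df = pd.DataFrame(
        [
            (e.participant_id, e.total_hours, e.level, e.hazardous)
            for e in exposures
        ],
        columns=["participant_id", "total_hours", "level_dba", "hazardous"],
    )
    scores = [hearing_score(p.hearing_items, p.participant_id) for p in eligible]
    score_df = pd.DataFrame(
        [(s.participant_id, s.points, s.classification, s.band) for s in scores],
        columns=["participant_id", "points", "classification", "band"],
    )
    log.info("stage exposure+scoring: %d hazardous of %d", int(exp_df["hazardous"].sum()), n)

    hazardous_ids = set(exp_df.loc[exp_df["hazardous"], "participant_id"])

    def is_hazardous(p: Participant) -> bool:
        return p.participant_id in hazardous_ids

    associations: list[dict] = []
    adjusted: dict = {}
    if n > 0:
        prevalence = symptom_prevalence(eligible, config.confidence, config.ci_method)
        bands = score_distribution(eligible)
        outcome_fns = {
            "tinnitus": lambda p: p.neq_tinnitus,
            "earache": lambda p: p.neq_earache,
            "temporary_loss": lambda p: p.neq_temporary_loss,
            "probable_hearing_loss": _probable_loss,
        }
        for name, fn in outcome_fns.items():
            associations.append(
                _association_row(
                    eligible, name, f"weekly_level_gt_{config.threshold_dba:g}_dba",
                    is_hazardous, fn, config.confidence,
                )
            )
        associations.append(
            _association_row(
                eligible, "probable_hearing_loss", "female_sex",
                lambda p: p.sex == "female", _probable_loss, config.confidence,
            )
        )
        associations.append(
            _association_row(
                eligible, "probable_hearing_loss", "noisy_residence",
                lambda p: p.noisy_residence, _probable_loss, config.confidence,
            )
        )
        strata = []
        for sex in ("female", "male"):
            members = [p for p in eligible if p.sex == sex]
            if members:
                sub = Cohort(tuple(members), eligible.catalog)
                strata.append(build_table(sub, is_hazardous, _probable_loss))
        try:
            adjusted = {
                "outcome": "probable_hearing_loss",
                "exposure": f"weekly_level_gt_{config.threshold_dba:g}_dba",
                "stratified_by": "sex",
                "odds_ratio": mantel_haenszel(strata),
                "strata": [
                    {"a": t.a, "b": t.b, "c": t.c, "d": t.d} for t in strata
                ],
            }
        except (ZeroDivisionError, ValueError) as exc:
            adjusted = {"error": str(exc)}
    else:
        prevalence = pd.DataFrame(
            columns=["item", "label", "count", "n", "percent", "ci_low", "ci_high"]
        )
        bands = pd.DataFrame(columns=["band", "count", "percent"])
    log.info("stage associations: %d tables", len(associations))

    sex_counts = {"female": 0, "male": 0}
    ages: list[int] = []
    for p in eligible:
        sex_counts[p.sex] += 1
        ages.append(p.age)

    catalog_digest = hashlib.sha256(
        catalog.to_frame().to_csv(index=False).encode()
    ).hexdigest()

    data = {
        "cohort": {
            "n_input": len(cohort),
            "n_excluded": len(exclusions),
            "n_retained": n,
            "exclusion_reasons": reason_counts,
            "exclusions": [
                {"participant_id": e.participant_id, "reason": e.reason}
                for e in exclusions
            ],
            "sex_counts": sex_counts,
            "age_median": float(pd.Series(ages).median()) if ages else None,
        },
        "exposure": {
            "reference_hours": summary.reference_hours,
            "threshold_dba": summary.threshold,
            "n_exposed": summary.n_exposed,
            "median_level_dba": summary.median_level,
            "pct_hazardous": summary.pct_hazardous,
            "pct_hazardous_by_sex": summary.pct_hazardous_by_sex,
            "mean_hours_per_activity": summary.mean_hours_per_activity,
        },
        "prevalence": prevalence.to_dict(orient="records"),
        "score_distribution": bands.to_dict(orient="records"),
        "associations": associations,
        "sex_adjusted": adjusted,
        "provenance": {
            "software": "leisurenoise",
            "version": _pkg_version,
            "catalog_sha256": catalog_digest,
            "probable_loss_cutoff": PROBABLE_LOSS_CUTOFF,
            "config": {
                "threshold_dba": config.threshold_dba,
                "reference_hours": config.reference_hours,
                "age_range": list(config.age_range),
                "ci_method": config.ci_method,
                "confidence": config.confidence,
            },
            "simulation_seed": source.seed if isinstance(source, SimulationConfig) else None,
        },
    }
    return AnalysisReport(data, exp_df, score_df)


def render_tables(report: AnalysisReport) -> str:
    """Human-readable analogs of the prevalence and association tables.

    Odds ratios and confidence limits are displayed to 2 decimals, levels
    to 1, percentages to the nearest integer — matching the machine-
    readable report after display rounding.
    """
    lines: list[str] = []
    exp = report.data["exposure"]
    lines.append("== Weekly exposure ==")
    med = exp["median_level_dba"]
    pct = exp["pct_hazardous"]
    lines.append(
        f"median level: {med:.1f} dBA (T0={exp['reference_hours']:g} h)"
        if med is not None else "median level: no exposed participants"
    )
    if pct is not None:
        lines.append(f"hazardous (> {exp['threshold_dba']:g} dBA): {round(pct)}%")
    lines.append("")
    lines.append("== Symptom prevalence ==")
    lines.append("item,count,n,percent,ci_low,ci_high")
    for row in report.data["prevalence"]:
        lines.append(
            f"{row['item']},{row['count']},{row['n']},{round(row['percent'])},"
            f"{row['ci_low']:.1f},{row['ci_high']:.1f}"
        )
    lines.append("")
    lines.append("== Associations ==")
    lines.append("outcome,exposure,a,b,c,d,or,ci_low,ci_high,chi2,p")
    for r in report.data["associations"]:
        lines.append(
            f"{r['outcome']},{r['exposure']},{r['a']},{r['b']},{r['c']},{r['d']},"
            f"{r['odds_ratio']:.2f},{r['ci_low']:.2f},{r['ci_high']:.2f},"
            f"{r['chi2']:.2f},{r['p_value']:.4f}"
        )
    adj = report.data["sex_adjusted"]
    if adj and "odds_ratio" in adj:
        lines.append("")
        lines.append(
            f"sex-adjusted (Mantel-Haenszel) OR for {adj['outcome']}: "
            f"{adj['odds_ratio']:.2f}"
        )
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """Write report.json, rendered tables, and per-participant intermediates."""
    out = Path(out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(render_tables(report))
    report.participant_exposures.to_csv(tables / "participant_exposure.csv", index=False)
    report.participant_scores.to_csv(tables / "participant_scores.csv", index=False)
    pd.DataFrame(report.data["prevalence"]).to_csv(tables / "prevalence.csv", index=False)
    pd.DataFrame(report.data["associations"]).to_csv(tables / "associations.csv", index=False)
    pd.DataFrame(report.data["score_distribution"]).to_csv(
        tables / "score_distribution.csv", index=False
    )
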