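"""Weekly equivalent noise level (LAeq) from questionnaire ratings.

The dosimetry model: each activity's subjective loudness rating r in 1..5
maps to a level L = laeq_max − 10·(5 − r) dBA, so one rating point is worth
10 dB.  Per-activity weekly durations t_i (hours) and levels L_i combine by
energy averaging over a reference time T0,

    L_week = 10·log10( (1/T0) · Σ_i t_i · 10^(L_i / 10) ),

the 3-dB-exchange-rate rule under which doubling the exposure time is
equivalent to a 3 dB level increase.  T0 defaults to a 40-hour occupational
reference week, matching the 85 dBA occupational limit the weekly level is
compared against; a participant is classified hazardous when their weekly
level is strictly above the threshold.  A participant with no noisy leisure
at all has no level (``None``), never 0 dBA — 0 dBA is a valid, very quiet
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .catalog import ActivityDef, Catalog
from .cohort import Cohort, ExposureRecord, Participant

__all__ = [
    "WeeklyExposure",
    "ExposureSummary",
    "rating_to_level",
    "weekly_duration",
    "weekly_equivalent_level",
    "classify_hazard",
    "participant_exposure",
    "exposure_summary",
    "DEFAULT_THRESHOLD_DBA",
    "DEFAULT_REFERENCE_HOURS",
]

DEFAULT_THRESHOLD_DBA = 85.0
DEFAULT_REFERENCE_HOURS = 40.0
DB_PER_RATING_POINT = 10.0


@dataclass(frozen=True)
class WeeklyExposure:
    """One participant's energy-averaged weekly exposure.

    ``level`` is ``None`` for a participant with zero noisy leisure hours
    (the "no exposure" state); such a participant is never hazardous.
    """

    participant_id: str
    level: float | None
    total_hours: float
    hazardous: bool


def rating_to_level(activity: ActivityDef, rating: int) -> float:
    """Convert a 1–5 subjective loudness rating to a level in dBA.

    Rating 5 receives the activity's maximum LAeq; every point below 5
    subtracts 10 dB (e.g. a 100-dBA activity gives 90 dBA at rating 4 and
    60 dBA at rating 1).
    """
    if rating not in (1, 2, 3, 4, 5):
        raise ValueError(f"loudness rating must be in 1..5, got {rating!r}")
    return activity.laeq_max - DB_PER_RATING_POINT * (5 - rating)


def weekly_duration(record: ExposureRecord) -> float:
    """Hours per week spent on the activity."""
    return record.hours_per_day * record.days_per_week


def weekly_equivalent_level(
    records: Iterable[ExposureRecord],
    catalog: Catalog,
    reference_hours: float = DEFAULT_REFERENCE_HOURS,
) -> float | None:
    """Energy-average the per-activity exposures over ``reference_hours``.

    Returns ``None`` when the total weekly duration is zero.
    """
    if reference_hours <= 0:
        raise ValueError("reference_hours must be positive")
    energy = 0.0  # Σ t_i · 10^(L_i/10), linear-energy · hours
    total = 0.0
    for rec in records:
        t = weekly_duration(rec)
        if t == 0.0:
            continue
        level = rating_to_level(catalog[rec.activity_id], rec.loudness_rating)
        energy += t * 10.0 ** (level / 10.0)
        total += t
    if total == 0.0:
        return None
    return 10.0 * math.log10(energy / reference_hours)


def classify_hazard(level: float | None, threshold: float = DEFAULT_THRESHOLD_DBA) -> bool:
    """True iff the weekly level is strictly above the permissible limit."""
    return level is not None and level > threshold


def participant_exposure(
    participant: Participant,
    catalog: Catalog,
    reference_hours: float = DEFAULT_REFERENCE_HOURS,
    threshold: float = DEFAULT_THRESHOLD_DBA,
) -> WeeklyExposure:
    level = weekly_equivalent_level(participant.exposures, catalog, reference_hours)
    total = sum(weekly_duration(r) for r in participant.exposures)
    return WeeklyExposure(
        participant_id=participant.participant_id,
        level=level,
        total_hours=total,
        hazardous=classify_hazard(level, threshold),
    )


@dataclass(frozen=True)
class ExposureSummary:
    """Cohort-level descriptives of the weekly exposure distribution.

    ``median_level`` is the median over participants with any exposure;
    percentages use the full participant count as denominator.
    """

    n: int
    n_exposed: int
    median_level: float | None
    pct_hazardous: float | None
    pct_hazardous_by_sex: dict[str, float | None]
    mean_hours_per_activity: dict[str, float]
    reference_hours: float
    threshold: float


def _pct(k: int, n: int) -> float | None:
    return 100.0 * k / n if n else None


def exposure_summary(
    cohort: Cohort,
    reference_hours: float = DEFAULT_REFERENCE_HOURS,
    threshold: float = DEFAULT_THRESHOLD_DBA,
) -> tuple[list[WeeklyExposure], ExposureSummary]:
    """Per-participant weekly exposures plus the cohort summary.

    The summary is fully recomputable from the returned per-participant
    exposures; an empty cohort yields an empty summary, never a division
    by zero.
    """
    exposures = [
        participant_exposure(p, cohort.catalog, reference_hours, threshold)
        for p in cohort.participants
    ]
    n = len(exposures)
    levels = sorted(e.level for e in exposures if e.level is not None)
    median = _median(levels) if levels else None
    n_haz = sum(e.hazardous for e in exposures)

    by_sex: dict[str, float | None] = {}
    for sex in ("female", "male"):
        idx = [i for i, p in enumerate(cohort.participants) if p.sex == sex]
        by_sex[sex] = _pct(sum(exposures[i].hazardous for i in idx), len(idx))

    hours: dict[str, float] = {aid: 0.0 for aid in cohort.catalog.ids}
    for p in cohort.participants:
        for rec in p.exposures:
            hours[rec.activity_id] += weekly_duration(rec)
    mean_hours = {aid: (h / n if n else 0.0) for aid, h in hours.items()}

    return exposures, ExposureSummary(
        n=n,
        n_exposed=len(levels),
        median_level=median,
        pct_hazardous=_pct(n_haz, n),
        pct_hazardous_by_sex=by_sex,
        mean_hours_per_activity=mean_hours,
        reference_hours=reference_hours,
        threshold=threshold,
    )


def _median(sorted_values: Sequence[float]) -> float:
    m = len(sorted_values)
    mid = m // 2
    if m % 2:
        return sorted_values[mid]
    return 0.5 * (sorted_values[mid - 1] + sorted_values[mid])
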