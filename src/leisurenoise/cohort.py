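"""Survey data model, CSV I/O, validation, and the eligibility filter.

One survey respondent is one row of a wide CSV: demographics, then three
columns per catalog activity (``<activity_id>_hours``, ``<activity_id>_days``,
``<activity_id>_rating``), then the three ear symptoms and the eleven
hearing-questionnaire items.  Yes/no answers are encoded 1/0.  A missing
rating with zero duration means "does not take part in this activity";
a positive duration without a rating is a validation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .catalog import Catalog

__all__ = [
    "ExposureRecord",
    "Participant",
    "Cohort",
    "Exclusion",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "N_HEARING_ITEMS",
]

N_HEARING_ITEMS = 11

DEMOGRAPHIC_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "program",
    "noisy_residence",
    "prior_hearing_diagnosis",
    "consent_given",
]
NEQ_SYMPTOM_COLUMNS = ["neq_tinnitus", "neq_earache", "neq_temporary_loss"]
HEARING_ITEM_COLUMNS = [f"hearing_item_{i}" for i in range(1, N_HEARING_ITEMS + 1)]


class SchemaError(ValueError):
    """The survey file is missing a required column or has the wrong layout."""


class CohortValidationError(ValueError):
    """A survey row holds an out-of-range or inconsistent value."""


@dataclass(frozen=True)
class ExposureRecord:
    """Participation in one leisure activity.

    ``loudness_rating`` is the respondent's subjective 1 ("very quiet") to
    5 ("very noisy") judgement; it may be absent only when the weekly
    duration is zero.
    """

    activity_id: str
    hours_per_day: float
    days_per_week: int
    loudness_rating: int | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hours_per_day <= 24.0:
            raise CohortValidationError(
                f"{self.activity_id}: hours_per_day {self.hours_per_day} outside [0, 24]"
            )
        if self.days_per_week not in range(0, 8):
            raise CohortValidationError(
                f"{self.activity_id}: days_per_week {self.days_per_week} outside [0, 7]"
            )
        if self.loudness_rating is not None and self.loudness_rating not in range(1, 6):
            raise CohortValidationError(
                f"{self.activity_id}: loudness_rating {self.loudness_rating} outside [1, 5]"
            )
        if self.hours_per_day * self.days_per_week > 0 and self.loudness_rating is None:
            raise CohortValidationError(
                f"{self.activity_id}: loudness rating required when weekly duration > 0"
            )


@dataclass(frozen=True)
class Participant:
    """One survey respondent."""

    participant_id: str
    age: int
    sex: str  # "female" | "male"
    program: str
    noisy_residence: bool
    prior_hearing_diagnosis: bool
    consent_given: bool
    exposures: tuple[ExposureRecord, ...]
    neq_tinnitus: bool
    neq_earache: bool
    neq_temporary_loss: bool
    hearing_items: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise CohortValidationError(
                f"{self.participant_id}: sex must be 'female' or 'male', got {self.sex!r}"
            )
        if len(self.hearing_items) != N_HEARING_ITEMS:
            raise CohortValidationError(
                f"{self.participant_id}: expected {N_HEARING_ITEMS} hearing items, "
                f"got {len(self.hearing_items)}"
            )
        ids = [e.activity_id for e in self.exposures]
        if len(ids) != len(set(ids)):
            raise CohortValidationError(
                f"{self.participant_id}: more than one exposure record per activity"
            )
        # canonical ordering makes equality independent of input record order
        object.__setattr__(
            self,
            "exposures",
            tuple(sorted(self.exposures, key=lambda e: e.activity_id)),
        )


@dataclass(frozen=True)
class Cohort:
    """A validated collection of participants plus the activity catalog."""

    participants: tuple[Participant, ...]
    catalog: Catalog

    def __post_init__(self) -> None:
        for p in self.participants:
            for rec in p.exposures:
                if rec.activity_id not in self.catalog:
                    raise CohortValidationError(
                        f"{p.participant_id}: exposure references unknown "
                        f"activity {rec.activity_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    reason: str


def _survey_columns(catalog: Catalog) -> list[str]:
    cols = list(DEMOGRAPHIC_COLUMNS)
    for aid in catalog.ids:
        cols += [f"{aid}_hours", f"{aid}_days", f"{aid}_rating"]
    return cols + NEQ_SYMPTOM_COLUMNS + HEARING_ITEM_COLUMNS


def _as_bool(value, column: str, pid: str) -> bool:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise CohortValidationError(
            f"{pid}: column {column} must be 0/1, got {value!r}"
        ) from None
    if iv not in (0, 1):
        raise CohortValidationError(f"{pid}: column {column} must be 0/1, got {value!r}")
    return bool(iv)


def read_cohort(path: str | Path, catalog: Catalog) -> Cohort:
    """Read and validate a wide-format survey CSV.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`CohortValidationError` (citing the row) when a value is out of
    range — no silent coercion.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = _survey_columns(catalog)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"survey file missing required column(s): {missing}")

    participants: list[Participant] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        r = dict(zip(df.columns, row))
        pid = r["participant_id"]
        try:
            exposures = []
            for aid in catalog.ids:
                hours = float(r[f"{aid}_hours"]) if r[f"{aid}_hours"] != "" else 0.0
                days = int(r[f"{aid}_days"]) if r[f"{aid}_days"] != "" else 0
                raw_rating = r[f"{aid}_rating"]
                rating = int(raw_rating) if raw_rating != "" else None
                if hours == 0.0 and days == 0 and rating is None:
                    continue  # non-participation: no record at all
                exposures.append(ExposureRecord(aid, hours, days, rating))
            participants.append(
                Participant(
                    participant_id=pid,
                    age=int(r["age"]),
                    sex=r["sex"],
                    program=r["program"],
                    noisy_residence=_as_bool(r["noisy_residence"], "noisy_residence", pid),
                    prior_hearing_diagnosis=_as_bool(
                        r["prior_hearing_diagnosis"], "prior_hearing_diagnosis", pid
                    ),
                    consent_given=_as_bool(r["consent_given"], "consent_given", pid),
                    exposures=tuple(exposures),
                    neq_tinnitus=_as_bool(r["neq_tinnitus"], "neq_tinnitus", pid),
                    neq_earache=_as_bool(r["neq_earache"], "neq_earache", pid),
                    neq_temporary_loss=_as_bool(
                        r["neq_temporary_loss"], "neq_temporary_loss", pid
                    ),
                    hearing_items=tuple(
                        _as_bool(r[c], c, pid) for c in HEARING_ITEM_COLUMNS
                    ),
                )
            )
        except (CohortValidationError, ValueError) as exc:
            raise CohortValidationError(
                f"row {idx} (participant {pid!r}): {exc}"
            ) from None
    return Cohort(tuple(participants), catalog)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the CSV dialect :func:`read_cohort` accepts; read∘write is identity."""
    cols = _survey_columns(cohort.catalog)
    rows = []
    for p in cohort.participants:
        by_aid = {e.activity_id: e for e in p.exposures}
        row: dict[str, object] = {
            "participant_id": p.participant_id,
            "age": p.age,
            "sex": p.sex,
            "program": p.program,
            "noisy_residence": int(p.noisy_residence),
            "prior_hearing_diagnosis": int(p.prior_hearing_diagnosis),
            "consent_given": int(p.consent_given),
            "neq_tinnitus": int(p.neq_tinnitus),
            "neq_earache": int(p.neq_earache),
            "neq_temporary_loss": int(p.neq_temporary_loss),
        }
        for aid in cohort.catalog.ids:
            rec = by_aid.get(aid)
            row[f"{aid}_hours"] = repr(rec.hours_per_day) if rec else ""
            row[f"{aid}_days"] = rec.days_per_week if rec else ""
            row[f"{aid}_rating"] = (
                rec.loudness_rating if rec and rec.loudness_rating is not None else ""
            )
        for i, ans in enumerate(p.hearing_items, start=1):
            row[f"hearing_item_{i}"] = int(ans)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def apply_eligibility(
    cohort: Cohort, age_range: tuple[int, int] = (18, 29)
) -> tuple[Cohort, list[Exclusion]]:
    """Drop ineligible participants; return the retained cohort and a report.

    A participant is excluded for a withheld consent, a previously diagnosed
    hearing problem, or an age outside ``age_range`` (inclusive).  Exactly
    one reason is recorded per excluded participant, in that priority
    order, so retained + excluded always partitions the input.
    """
    lo, hi = age_range
    retained: list[Participant] = []
    excluded: list[Exclusion] = []
    for p in cohort.participants:
        if not p.consent_given:
            excluded.append(Exclusion(p.participant_id, "consent_withheld"))
        elif p.prior_hearing_diagnosis:
            excluded.append(Exclusion(p.participant_id, "prior_hearing_diagnosis"))
        elif not lo <= p.age <= hi:
            excluded.append(Exclusion(p.participant_id, f"age_outside_[{lo},{hi}]"))
        else:
            retained.append(p)
    return Cohort(tuple(retained), cohort.catalog), excluded
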