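"""Activity catalog: leisure activities and their maximum equivalent sound levels.

Each catalog entry assigns one leisure-noise activity the A-weighted
equivalent continuous sound level (LAeq, in dBA) that corresponds to the
loudest subjective rating on the questionnaire's five-point scale.  The
shipped default catalog covers the ten classic leisure activities from the
noise-exposure-questionnaire literature plus three survey activities
(television, video games, bars) mapped onto acoustically comparable
entries; the mapping lives in the CSV, not in code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = ["ActivityDef", "Catalog", "load_catalog", "default_catalog"]

#: Plausible physical range for a leisure activity's maximum LAeq, in dBA.
LAEQ_BOUNDS = (60.0, 140.0)


@dataclass(frozen=True)
class ActivityDef:
    """One leisure activity and the sound level assigned to rating 5.

    Parameters
    ----------
    activity_id
        Short stable token used to reference the activity in survey columns.
    label
        Human-readable display name.
    laeq_max
        Maximum equivalent continuous sound level in dBA; the level a
        respondent experiences when rating the activity 5 ("very noisy").
    """

    activity_id: str
    label: str
    laeq_max: float

    def __post_init__(self) -> None:
        if not self.activity_id or not self.activity_id.strip():
            raise ValueError("activity_id must be a non-empty token")
        if not math.isfinite(self.laeq_max):
            raise ValueError(f"{self.activity_id}: laeq_max must be finite")
        lo, hi = LAEQ_BOUNDS
        if not (lo <= self.laeq_max <= hi):
            raise ValueError(
                f"{self.activity_id}: laeq_max {self.laeq_max} dBA outside "
                f"plausible range [{lo}, {hi}]"
            )


class Catalog:
    """Immutable collection of :class:`ActivityDef` keyed by ``activity_id``."""

    def __init__(self, activities: list[ActivityDef] | tuple[ActivityDef, ...]):
        seen: dict[str, ActivityDef] = {}
        for act in activities:
            if act.activity_id in seen:
                raise ValueError(f"duplicate activity_id {act.activity_id!r}")
            seen[act.activity_id] = act
        self._by_id = seen

    def __getitem__(self, activity_id: str) -> ActivityDef:
        try:
            return self._by_id[activity_id]
        except KeyError:
            raise KeyError(f"unknown activity_id {activity_id!r}") from None

    def __contains__(self, activity_id: str) -> bool:
        return activity_id in self._by_id

    def __iter__(self) -> Iterator[ActivityDef]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.activity_id, a.label, a.laeq_max) for a in self],
            columns=["activity_id", "label", "laeq_max"],
        )


def load_catalog(path: str | Path) -> Catalog:
    """Read an activity catalog from a CSV with columns activity_id,label,laeq_max."""
    df = pd.read_csv(path)
    required = {"activity_id", "label", "laeq_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog file missing columns: {sorted(missing)}")
    return Catalog(
        [
            ActivityDef(str(r.activity_id), str(r.label), float(r.laeq_max))
            for r in df.itertuples()
        ]
    )


def default_catalog() -> Catalog:
    """The shipped default catalog (ten reference activities + three mapped ones)."""
    with resources.as_file(
        resources.files("leisurenoise.data").joinpath("default_catalog.csv")
    ) as p:
        return load_catalog(p)
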