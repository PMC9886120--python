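"""Hearing-symptom scoring and probable-hearing-loss classification.

The hearing questionnaire has eleven yes/no items; each affirmative answer
scores one point (0–11).  Four or more points classifies the respondent as
having probable hearing loss of some degree; 0–3 points as no suspicion of
hearing loss.  Scores are also banded 0 / 1–3 / 4–6 / 7–11 for reporting.
The three ear symptoms recorded alongside (tinnitus, earache, temporary
hearing loss after noise) are simple binary flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, Participant, N_HEARING_ITEMS

__all__ = [
    "HearingScore",
    "HEARING_ITEM_LABELS",
    "PROBABLE_LOSS_CUTOFF",
    "SCORE_BANDS",
    "hearing_score",
    "neq_symptom_flags",
    "proportion_ci",
    "symptom_prevalence",
    "score_distribution",
]

PROBABLE_LOSS_CUTOFF = 4  # points; >= 4 means probable hearing loss

#: Band label for every possible score, reporting order.
SCORE_BANDS = ("0", "1-3", "4-6", "7-11")

#: Display labels for the eleven items, in questionnaire order.
HEARING_ITEM_LABELS = (
    "Difficulty understanding speech in noisy or crowded places",
    "Needs to ask others to repeat what they said",
    "Difficulty understanding speech in a car or other noisy setting",
    "Feels stressed or tired after listening for a long time",
    "Turns the TV volume up louder than others",
    "Feels that others mumble or do not speak clearly",
    "Needs to be very close to a speaker to hear",
    "Difficulty hearing people who are not facing them",
    "Avoids parties or events because of hearing problems",
    "Has been asked about possible hearing problems",
    "Difficulty identifying where a sound comes from",
)


@dataclass(frozen=True)
class HearingScore:
    participant_id: str
    points: int
    classification: str  # "probable_hearing_loss" | "no_suspicion"
    band: str


def _band(points: int) -> str:
    if points == 0:
        return "0"
    if points <= 3:
        return "1-3"
    if points <= 6:
        return "4-6"
    return "7-11"


def hearing_score(
    items: Sequence[bool], participant_id: str = ""
) -> HearingScore:
    """Score eleven yes/no answers and classify probable hearing loss."""
    if len(items) != N_HEARING_ITEMS:
        raise ValueError(
            f"expected {N_HEARING_ITEMS} hearing items, got {len(items)}"
        )
    points = int(sum(bool(x) for x in items))
    classification = (
        "probable_hearing_loss" if points >= PROBABLE_LOSS_CUTOFF else "no_suspicion"
    )
    return HearingScore(participant_id, points, classification, _band(points))


def neq_symptom_flags(participant: Participant) -> dict[str, bool]:
    """The three ear-symptom flags with stable labels."""
    return {
        "tinnitus": participant.neq_tinnitus,
        "earache": participant.neq_earache,
        "temporary_loss": participant.neq_temporary_loss,
    }


def proportion_ci(
    count: int, n: int, confidence: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion, on the proportion scale.

    ``method`` is ``"wald"`` (normal approximation, the default used for
    prevalence tables) or ``"wilson"``.  Bounds are clipped to [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    z = norm.ppf(0.5 + confidence / 2.0)
    p = count / n
    if method == "wald":
        half = z * math.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1.0 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = centre - half, centre + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return max(0.0, lo), min(1.0, hi)


def symptom_prevalence(
    cohort: Cohort, confidence: float = 0.95, method: str = "wald"
) -> pd.DataFrame:
    """Prevalence table: 11 hearing items, 3 ear symptoms, and "any item".

    Returns a tidy frame with columns ``item``, ``label``, ``count``, ``n``,
    ``percent`` (0–100 scale, unrounded), ``ci_low``, ``ci_high`` (percent
    scale).
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot compute prevalences for an empty cohort")
    rows: list[tuple[str, str, int]] = []
    for i, label in enumerate(HEARING_ITEM_LABELS):
        count = sum(p.hearing_items[i] for p in cohort)
        rows.append((f"hearing_item_{i + 1}", label, count))
    rows.append(
        (
            "any_hearing_item",
            "At least one hearing item affirmed",
            sum(any(p.hearing_items) for p in cohort),
        )
    )
    for key, label in (
        ("neq_tinnitus", "Ringing in the ears (tinnitus)"),
        ("neq_earache", "Earache"),
        ("neq_temporary_loss", "Temporary hearing loss after noise"),
    ):
        rows.append((key, label, sum(getattr(p, key) for p in cohort)))

    out = []
    for item, label, count in rows:
        lo, hi = proportion_ci(count, n, confidence, method)
        out.append((item, label, count, n, 100.0 * count / n, 100.0 * lo, 100.0 * hi))
    return pd.DataFrame(
        out, columns=["item", "label", "count", "n", "percent", "ci_low", "ci_high"]
    )


def score_distribution(cohort: Cohort) -> pd.DataFrame:
    """Counts and percentages of participants per score band (bands sum to n)."""
    n = len(cohort)
    counts = {band: 0 for band in SCORE_BANDS}
    for p in cohort:
        counts[hearing_score(p.hearing_items, p.participant_id).band] += 1
    return pd.DataFrame(
        [
            (band, counts[band], 100.0 * counts[band] / n if n else 0.0)
            for band in SCORE_BANDS
        ],
        columns=["band", "count", "percent"],
    )
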