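"""Association statistics for 2×2 exposure × outcome tables.

Implements the estimators a cross-sectional questionnaire study reports:
the odds ratio with Woolf (log-normal) confidence limits, the Pearson
chi-square test of independence (optionally Yates-corrected), the
Mantel–Haenszel pooled odds ratio across confounder strata, and the
prevalence-survey sample-size formula with finite-population correction
and design effect.

Zero cells are handled by the Haldane–Anscombe correction (+0.5 to every
cell) and flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm

from .cohort import Cohort, Participant

__all__ = [
    "TwoByTwo",
    "AssociationResult",
    "build_table",
    "odds_ratio",
    "woolf_ci",
    "chi_square",
    "associate",
    "mantel_haenszel",
    "sample_size",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure × outcome contingency counts.

    a: exposed with outcome, b: exposed without, c: unexposed with,
    d: unexposed without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("table must have at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def corrected_cells(self) -> tuple[float, float, float, float]:
        """Cells after Haldane–Anscombe +0.5 correction (applied only if needed)."""
        if self.has_zero_cell:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2_statistic: float
    p_value: float
    continuity_corrected: bool
    zero_cell_corrected: bool
    table: TwoByTwo


def build_table(
    cohort: Cohort,
    exposure_indicator: Callable[[Participant], bool],
    outcome_indicator: Callable[[Participant], bool],
) -> TwoByTwo:
    """Cross-tabulate two boolean participant indicators."""
    if len(cohort) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    a = b = c = d = 0
    for p in cohort:
        exposed = bool(exposure_indicator(p))
        outcome = bool(outcome_indicator(p))
        if exposed and outcome:
            a += 1
        elif exposed:
            b += 1
        elif outcome:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


def odds_ratio(table: TwoByTwo) -> float:
    """Cross-product odds ratio (a·d)/(b·c), Haldane-corrected on zero cells."""
    a, b, c, d = table.corrected_cells()
    return (a * d) / (b * c)


def woolf_ci(table: TwoByTwo, confidence: float = 0.95) -> tuple[float, float]:
    """Woolf log-normal confidence limits for the odds ratio.

    exp( ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d) ), with the normal quantile
    computed from ``confidence``; zero cells use the corrected counts.
    """
    if not 0.0 <= confidence < 1.0:
        raise ValueError("confidence must be in [0, 1)")
    a, b, c, d = table.corrected_cells()
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _norm.ppf(0.5 + confidence / 2.0)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def chi_square(table: TwoByTwo, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (1 df) for a 2×2 table.

    statistic = n·(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)); with Yates
    continuity correction, |ad − bc| is first reduced by n/2 (floored at
    zero).  A zero margin makes the test undefined; (nan, nan) is
    returned.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return (math.nan, math.nan)
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff * diff / denom
    return stat, float(_chi2_dist.sf(stat, df=1))


def associate(
    table: TwoByTwo, confidence: float = 0.95, yates: bool = False
) -> AssociationResult:
    """Odds ratio, Woolf CI, and chi-square test bundled for reporting."""
    lo, hi = woolf_ci(table, confidence)
    stat, p = chi_square(table, yates)
    return AssociationResult(
        odds_ratio=odds_ratio(table),
        ci_low=lo,
        ci_high=hi,
        chi2_statistic=stat,
        p_value=p,
        continuity_corrected=yates,
        zero_cell_corrected=table.has_zero_cell,
        table=table,
    )


def mantel_haenszel(strata: Sequence[TwoByTwo]) -> float:
    """Mantel–Haenszel pooled odds ratio Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ).

    A single stratum reduces to the crude odds ratio.  Raises when the
    denominator is zero across all strata (the estimator is undefined).
    """
    if not strata:
        raise ValueError("at least one stratum is required")
    num = sum(t.a * t.d / t.n for t in strata)
    den = sum(t.b * t.c / t.n for t in strata)
    if den == 0.0:
        raise ZeroDivisionError("Mantel–Haenszel denominator is zero in every stratum")
    return num / den


def sample_size(
    population: int,
    expected_proportion: float,
    precision: float,
    confidence: float = 0.95,
    design_effect: float = 1.0,
) -> int:
    """Sample size for estimating a prevalence in a finite population.

    n0 = z²·p·(1−p)/d² is corrected for the finite population,
    n = n0 / (1 + n0/N), then inflated by the design effect and rounded
    up.  The finite-population correction is applied before the design
    effect.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0.0 < expected_proportion < 1.0:
        raise ValueError("expected_proportion must be in (0, 1)")
    if precision <= 0.0:
        raise ValueError("precision must be positive")
    if design_effect <= 0.0:
        raise ValueError("design_effect must be positive")
    z = _norm.ppf(0.5 + confidence / 2.0)
    p = expected_proportion
    n0 = z * z * p * (1.0 - p) / (precision * precision)
    n_fpc = n0 / (1.0 + n0 / population)
    return math.ceil(n_fpc * design_effect)
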