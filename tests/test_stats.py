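"""Odds ratios, Woolf intervals, chi-square, Mantel–Haenszel, sample size."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency, norm
from statsmodels.stats.contingency_tables import StratifiedTable, Table2x2

from leisurenoise import (
    Cohort,
    TwoByTwo,
    associate,
    build_table,
    chi_square,
    mantel_haenszel,
    odds_ratio,
    sample_size,
    woolf_ci,
)

from conftest import make_participant

cells = st.integers(min_value=1, max_value=500)
tables = st.builds(TwoByTwo, cells, cells, cells, cells)


class TestTwoByTwo:
    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(1, -1, 1, 1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(0, 0, 0, 0)


class TestBuildTable:
    def test_margins_and_double_count(self, catalog):
        participants = tuple(
            make_participant(
                f"P{i}",
                sex="female" if i % 3 else "male",
                tinnitus=(i % 2 == 0),
            )
            for i in range(40)
        )
        cohort = Cohort(participants, catalog)
        expose = lambda p: p.sex == "female"
        outcome = lambda p: p.neq_tinnitus
        t = build_table(cohort, expose, outcome)
        # brute-force recount
        assert t.a == sum(expose(p) and outcome(p) for p in participants)
        assert t.a + t.b == sum(expose(p) for p in participants)
        assert t.a + t.c == sum(outcome(p) for p in participants)
        assert t.n == 40

    def test_false_outcome_empties_outcome_cells(self, small_cohort):
        t = build_table(small_cohort, lambda p: p.sex == "female", lambda p: False)
        assert t.a == 0 and t.c == 0

    def test_empty_cohort_raises(self, catalog):
        with pytest.raises(ValueError):
            build_table(Cohort((), catalog), lambda p: True, lambda p: True)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (TwoByTwo(217, 182, 135, 178), 1.57),
            (TwoByTwo(309, 90, 206, 107), 1.78),
            (TwoByTwo(200, 199, 115, 198), 1.73),
            (TwoByTwo(222, 203, 130, 157), 1.32),
            (TwoByTwo(1, 1, 1, 1), 1.0),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert round(odds_ratio(table), 2) == expected

    def test_haldane_correction_on_zero_cell(self):
        t = TwoByTwo(5, 0, 3, 4)
        assert odds_ratio(t) == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))
        assert associate(t).zero_cell_corrected

    @settings(deadline=None, max_examples=100)
    @given(t=tables)
    def test_transposing_exposure_inverts(self, t):
        flipped = TwoByTwo(t.b, t.a, t.d, t.c)
        assert odds_ratio(flipped) == pytest.approx(1.0 / odds_ratio(t), rel=1e-12)


class TestWoolfCI:
    def test_reference_interval(self):
        lo, hi = woolf_ci(TwoByTwo(217, 182, 135, 178))
        assert round(lo, 2) == 1.17 and round(hi, 2) == 2.12
        # interval contains the point estimate, width close to published 0.95
        assert lo <= odds_ratio(TwoByTwo(217, 182, 135, 178)) <= hi
        assert abs((hi - lo) - (2.11 - 1.16)) < 0.05

    @settings(deadline=None, max_examples=60)
    @given(t=tables)
    def test_against_statsmodels(self, t):
        lo, hi = woolf_ci(t)
        sm_lo, sm_hi = Table2x2(
            np.array([[t.a, t.b], [t.c, t.d]])
        ).oddsratio_confint(alpha=0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-9)
        assert hi == pytest.approx(sm_hi, rel=1e-9)

    def test_confidence_zero_collapses(self):
        t = TwoByTwo(10, 20, 30, 40)
        lo, hi = woolf_ci(t, confidence=0.0)
        assert lo == pytest.approx(odds_ratio(t)) and hi == pytest.approx(odds_ratio(t))


class TestChiSquare:
    def test_reference_statistic(self):
        stat, p = chi_square(TwoByTwo(217, 182, 135, 178))
        assert stat == pytest.approx(8.889, abs=0.001)
        assert p < 0.05

    def test_independent_table_is_zero(self):
        stat, p = chi_square(TwoByTwo(10, 20, 30, 60))  # ad == bc
        assert stat == 0.0 and p == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60)
    @given(t=tables)
    def test_against_scipy(self, t):
        arr = np.array([[t.a, t.b], [t.c, t.d]])
        for yates in (False, True):
            stat, p = chi_square(t, yates=yates)
            res = chi2_contingency(arr, correction=yates)
            assert stat == pytest.approx(res.statistic, rel=1e-10)
            assert p == pytest.approx(res.pvalue, rel=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(t=tables)
    def test_yates_never_exceeds_uncorrected(self, t):
        assert chi_square(t, yates=True)[0] <= chi_square(t, yates=False)[0] + 1e-12

    def test_zero_margin_undefined(self):
        stat, p = chi_square(TwoByTwo(0, 0, 3, 4))
        assert math.isnan(stat) and math.isnan(p)

    def test_matches_squared_z_on_large_balanced_table(self):
        # chi-square p and Wald log-OR z-test p agree asymptotically
        t = TwoByTwo(600, 400, 500, 500)
        stat, p_chi = chi_square(t)
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        z = math.log(odds_ratio(t)) / se
        p_z = 2 * norm.sf(abs(z))
        assert abs(p_chi - p_z) / p_z < 0.10


class TestMantelHaenszel:
    def test_single_stratum_is_crude(self):
        t = TwoByTwo(217, 182, 135, 178)
        assert mantel_haenszel([t]) == pytest.approx(odds_ratio(t))
        assert round(mantel_haenszel([t]), 2) == 1.57

    def test_two_identical_strata(self):
        t = TwoByTwo(20, 10, 5, 15)
        assert mantel_haenszel([t, t]) == pytest.approx(mantel_haenszel([t]))

    @settings(deadline=None, max_examples=60)
    @given(strata=st.lists(tables, min_size=1, max_size=4))
    def test_weighted_sum_oracle_and_statsmodels(self, strata):
        num = sum(t.a * t.d / (t.a + t.b + t.c + t.d) for t in strata)
        den = sum(t.b * t.c / (t.a + t.b + t.c + t.d) for t in strata)
        expected = num / den
        got = mantel_haenszel(strata)
        assert got == pytest.approx(expected, abs=1e-12, rel=1e-12)
        sm = StratifiedTable(
            [np.array([[t.a, t.b], [t.c, t.d]]) for t in strata]
        ).oddsratio_pooled
        assert got == pytest.approx(sm, rel=1e-10)

    def test_no_strata_raises(self):
        with pytest.raises(ValueError):
            mantel_haenszel([])


class TestSampleSize:
    def test_survey_design_values(self):
        assert sample_size(13431, 0.17, 0.03, 0.95, 1.2) == 692

    def test_recruitment_inflation(self):
        assert math.ceil(692 * 1.05) == 727  # enrolment padding arithmetic

    def test_infinite_population_limit(self):
        z = norm.ppf(0.975)
        expected = math.ceil(z * z * 0.17 * 0.83 / 0.03**2)
        assert sample_size(10**9, 0.17, 0.03, 0.95, 1.0) == expected

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(population=0, expected_proportion=0.2, precision=0.03),
            dict(population=100, expected_proportion=0.0, precision=0.03),
            dict(population=100, expected_proportion=0.2, precision=0.0),
            dict(population=100, expected_proportion=0.2, precision=0.03, design_effect=0),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            sample_size(**kwargs)
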