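"""Rating→level map and energy-averaged weekly exposure."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from leisurenoise import (
    Cohort,
    ExposureRecord,
    classify_hazard,
    exposure_summary,
    rating_to_level,
    weekly_duration,
    weekly_equivalent_level,
)

from conftest import loud_exposure, make_participant, quiet_exposure


class TestRatingToLevel:
    @pytest.mark.parametrize(
        "activity_id, rating, expected",
        [
            ("personal_stereo", 5, 100.0),
            ("personal_stereo", 4, 90.0),
            ("personal_stereo", 3, 80.0),
            ("personal_stereo", 2, 70.0),
            ("personal_stereo", 1, 60.0),
            ("disco", 1, 65.0),
        ],
    )
    def test_ten_db_per_point(self, catalog, activity_id, rating, expected):
        assert rating_to_level(catalog[activity_id], rating) == expected

    def test_ladder_spacing_for_every_activity(self, catalog):
        for act in catalog:
            levels = [rating_to_level(act, r) for r in range(1, 6)]
            assert levels[-1] == act.laeq_max
            assert all(b - a == 10.0 for a, b in zip(levels, levels[1:]))

    @pytest.mark.parametrize("bad", [0, 6, -1, 2.5])
    def test_out_of_range_rating(self, catalog, bad):
        with pytest.raises(ValueError):
            rating_to_level(catalog["disco"], bad)


class TestWeeklyDuration:
    @pytest.mark.parametrize(
        "hours, days, expected",
        [(2.0, 7, 14.0), (0.0, 5, 0.0), (2.57, 7, pytest.approx(17.99))],
    )
    def test_product(self, hours, days, expected):
        rec = ExposureRecord("tv", hours, days, 3 if hours else None)
        assert weekly_duration(rec) == expected


def _rec(aid: str, weekly_hours: float, rating: int) -> ExposureRecord:
    # encode an exact weekly duration as hours/day over 1 day
    assert weekly_hours <= 24
    return ExposureRecord(aid, weekly_hours, 1, rating)


class TestWeeklyEquivalentLevel:
    def test_identity_case(self, catalog):
        # 40 h/week at a constant level over a 40-h reference week is that level
        recs = [ExposureRecord("disco", 8.0, 5, 1)]  # 40 h at 65 dBA
        level = weekly_equivalent_level(recs, catalog, reference_hours=40.0)
        assert level == pytest.approx(65.0, abs=1e-12)

    def test_split_invariance(self, catalog):
        whole = [_rec("disco", 20.0, 3)]
        split = [_rec("disco", 12.0, 3), ExposureRecord("bars", 8.0, 1, 3)]
        # same level (85 dBA) through two activities vs one
        lv_whole = weekly_equivalent_level(
            whole + [ExposureRecord("bars", 0.0, 0, None)], catalog
        )
        lv_split = weekly_equivalent_level(split, catalog)
        assert lv_split == pytest.approx(lv_whole, abs=1e-9)

    def test_halving_time_drops_three_db(self, catalog):
        # 20 h at 85 dBA over T0=40 h: 85 - 10*log10(2) = 81.99 dBA
        lv = weekly_equivalent_level([_rec("disco", 20.0, 3)], catalog, 40.0)
        assert lv == pytest.approx(85.0 - 10.0 * math.log10(2.0), abs=1e-12)

    def test_no_records_is_sentinel(self, catalog):
        assert weekly_equivalent_level([], catalog) is None
        zero = [ExposureRecord("tv", 0.0, 0, None)]
        assert weekly_equivalent_level(zero, catalog) is None

    def test_unknown_activity_raises(self, catalog):
        with pytest.raises(KeyError):
            weekly_equivalent_level([_rec("karaoke", 2.0, 3)], catalog)

    def test_bad_reference_time(self, catalog):
        with pytest.raises(ValueError):
            weekly_equivalent_level([_rec("disco", 2.0, 3)], catalog, 0.0)


@st.composite
def record_sets(draw):
    aids = ["disco", "tv", "personal_stereo", "band", "bars"]
    n = draw(st.integers(1, 5))
    recs = []
    for i in range(n):
        hours = draw(st.floats(0.1, 11.9))
        days = draw(st.integers(1, 7))
        rating = draw(st.integers(1, 5))
        recs.append(ExposureRecord(aids[i % len(aids)], hours, days, rating))
    # one record per activity id
    seen, out = set(), []
    for r in recs:
        if r.activity_id not in seen:
            seen.add(r.activity_id)
            out.append(r)
    return out


class TestEnergyAveragingProperties:
    @settings(deadline=None, max_examples=100)
    @given(recs=record_sets())
    def test_brute_force_oracle(self, recs, catalog):
        """Log-domain result matches an hour-by-hour linear-energy sum."""
        from leisurenoise.exposure import rating_to_level as r2l

        t0 = 40.0
        # oracle: accumulate linear energy record by record, never in logs
        energy = 0.0
        for rec in recs:
            t = rec.hours_per_day * rec.days_per_week
            lvl = r2l(catalog[rec.activity_id], rec.loudness_rating)
            energy += t * 10.0 ** (lvl / 10.0)
        expected = 10.0 * math.log10(energy / t0)
        got = weekly_equivalent_level(recs, catalog, t0)
        assert got == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(recs=record_sets())
    def test_doubling_law(self, recs, catalog):
        """Doubling every duration raises the level by 10*log10(2) dB."""
        base = weekly_equivalent_level(recs, catalog)
        doubled = [
            ExposureRecord(r.activity_id, r.hours_per_day * 2, r.days_per_week, r.loudness_rating)
            for r in recs
        ]
        lv2 = weekly_equivalent_level(doubled, catalog)
        assert lv2 - base == pytest.approx(10.0 * math.log10(2.0), abs=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(recs=record_sets(), bump=st.floats(0.1, 5.0))
    def test_monotone_in_duration(self, recs, bump, catalog):
        base = weekly_equivalent_level(recs, catalog)
        r0 = recs[0]
        more = [
            ExposureRecord(
                r0.activity_id, min(24.0, r0.hours_per_day + bump),
                r0.days_per_week, r0.loudness_rating,
            )
        ] + recs[1:]
        assert weekly_equivalent_level(more, catalog) >= base - 1e-12


class TestHazardClassification:
    @pytest.mark.parametrize(
        "level, expected",
        [(87.0, True), (85.0, False), (85.0001, True), (None, False), (0.0, False)],
    )
    def test_strict_threshold(self, level, expected):
        assert classify_hazard(level) is expected


class TestExposureSummary:
    def test_all_hazardous(self, catalog):
        cohort = Cohort(
            tuple(make_participant(f"P{i}", exposures=loud_exposure()) for i in range(4)),
            catalog,
        )
        _, s = exposure_summary(cohort)
        assert s.pct_hazardous == 100.0

    def test_single_participant_median(self, catalog):
        cohort = Cohort((make_participant("P1", exposures=quiet_exposure()),), catalog)
        exps, s = exposure_summary(cohort)
        assert s.median_level == exps[0].level

    def test_empty_cohort_no_division(self, catalog):
        exps, s = exposure_summary(Cohort((), catalog))
        assert exps == [] and s.pct_hazardous is None and s.median_level is None

    def test_summary_recomputable_from_per_participant(self, small_cohort):
        exps, s = exposure_summary(small_cohort)
        assert s.pct_hazardous == pytest.approx(
            100.0 * sum(e.hazardous for e in exps) / len(exps)
        )
        assert s.n_exposed == sum(e.level is not None for e in exps)
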