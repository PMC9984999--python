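import datetime as dt

import numpy as np
import pytest

from vaxcast._dates import add_months, age_on
from vaxcast.engine import (
    ForecastError,
    Status,
    WarningKind,
    dose_status,
    forecast_visit,
    next_visit,
    record_administration,
    replay,
)
from vaxcast.gold import gold_due
from vaxcast.records import RecordError
from vaxcast.schedule import ServiceCalendar

from .conftest import make_child, random_child_and_visit

D = dt.date


class TestAgeArithmetic:
    def test_same_day_is_zero(self):
        assert age_on(D(2019, 1, 1), D(2019, 1, 1)) == 0

    def test_six_weeks_is_42_days(self):
        assert age_on(D(2019, 1, 1), D(2019, 2, 12)) == 42

    def test_calendar_month_clamps_short_months(self):
        assert add_months(D(2019, 1, 31), 1) == D(2019, 2, 28)
        assert add_months(D(2020, 1, 31), 1) == D(2020, 2, 29)

    def test_before_birth_rejected(self):
        with pytest.raises(ValueError):
            age_on(D(2019, 1, 2), D(2019, 1, 1))


class TestDoseStatus:
    def test_given_dose_reported_given(self, pakistan):
        child = make_child(doses=[("BCG", 1, "2019-07-01")])
        s = dose_status(child, pakistan.rule("BCG", 1), D(2019, 8, 1), pakistan)
        assert s.status is Status.GIVEN

    def test_birth_opv_not_indicated_at_day_40(self, pakistan):
        child = make_child()
        s = dose_status(child, pakistan.rule("OPV", 1), D(2019, 8, 10), pakistan)
        assert s.status is Status.NOT_INDICATED

    def test_measles2_scheduled_date_matches_brute_force(self, pakistan):
        # measles-1 ten days ago, child ~16 months: the interval, not the
        # age floor, binds. Oracle: scan the next 60 days for the first
        # date on which every constraint holds.
        dob = D(2018, 3, 10)
        visit = D(2019, 7, 10)
        m1 = visit - dt.timedelta(days=10)
        child = make_child(dob=dob, doses=[("Measles", 1, m1)])
        rule = pakistan.rule("Measles", 2)

        def ok(day):
            return (
                day >= add_months(dob, 15)
                and (day - m1).days >= 29
            )

        oracle = next(
            visit + dt.timedelta(days=k)
            for k in range(1, 61)
            if ok(visit + dt.timedelta(days=k))
        )
        s = dose_status(child, rule, visit, pakistan)
        assert s.status is Status.SCHEDULED
        assert s.scheduled_date == oracle == m1 + dt.timedelta(days=29)

    def test_chained_dose_without_prereq_in_history_is_error(self, pakistan):
        child = make_child(doses=[("Penta", 2, "2019-10-01")])
        with pytest.raises(ForecastError, match="Penta-2"):
            dose_status(child, pakistan.rule("Penta", 2), D(2019, 11, 1), pakistan)


class TestForecastVisit:
    def test_newborn_due_bcg_and_birth_opv(self, pakistan):
        f = forecast_visit(make_child(), D(2019, 7, 1), pakistan)
        assert f.due_now == {("BCG", 1), ("OPV", 1)}
        others = f.by_status(Status.SCHEDULED)
        assert len(others) == 14  # everything else scheduled, nothing not-indicated

    def test_day98_catchup_includes_ipv_by_age_alone(self, pakistan):
        child = make_child(doses=[("BCG", 1, "2019-07-01"), ("OPV", 1, "2019-07-01")])
        f = forecast_visit(child, D(2019, 10, 7), pakistan)  # day 98
        assert f.due_now == {
            ("Penta", 1), ("OPV", 2), ("PCV", 1), ("Rota", 1), ("IPV", 1),
        }

    def test_fully_vaccinated_two_year_old(self, pakistan):
        doses = [
            ("BCG", 1, "2019-07-01"), ("OPV", 1, "2019-07-01"),
            ("Penta", 1, "2019-08-12"), ("OPV", 2, "2019-08-12"),
            ("PCV", 1, "2019-08-12"), ("Rota", 1, "2019-08-12"),
            ("Penta", 2, "2019-09-10"), ("OPV", 3, "2019-09-10"),
            ("PCV", 2, "2019-09-10"), ("Rota", 2, "2019-09-10"),
            ("Penta", 3, "2019-10-08"), ("OPV", 4, "2019-10-08"),
            ("PCV", 3, "2019-10-08"), ("IPV", 1, "2019-10-08"),
            ("Measles", 1, "2020-04-01"), ("Measles", 2, "2020-10-01"),
        ]
        f = forecast_visit(make_child(doses=doses), D(2021, 7, 1), pakistan)
        assert f.by_status(Status.GIVEN) == set(pakistan.slots)
        assert f.next_visit_date is None

    def test_visit_before_birth_rejected(self, pakistan):
        with pytest.raises(ForecastError):
            forecast_visit(make_child(), D(2019, 6, 30), pakistan)


class TestNextVisit:
    def test_empty_pending_absent(self):
        assert next_visit([], None) is None

    def test_on_service_day_unchanged(self, pakistan):
        cal = ServiceCalendar(service_weekdays=frozenset(range(6)))
        f = forecast_visit(make_child(), D(2019, 7, 1), pakistan, cal)
        # earliest scheduled is the 6-week block on Monday 2019-08-12
        assert f.next_visit_date == D(2019, 8, 12)

    def test_holiday_rolls_to_next_service_day(self, pakistan):
        cal = ServiceCalendar(
            service_weekdays=frozenset(range(6)),
            public_holidays=frozenset({D(2019, 8, 12), D(2019, 8, 13)}),
        )
        f = forecast_visit(make_child(), D(2019, 7, 1), pakistan, cal)
        # Mon+Tue are holidays -> Wednesday; oracle by forward enumeration
        day = D(2019, 8, 12)
        while not cal.serves(day):
            day += dt.timedelta(days=1)
        assert f.next_visit_date == day == D(2019, 8, 14)

    def test_never_before_eligibility(self, pakistan):
        cal = ServiceCalendar(service_weekdays=frozenset({6}))  # Sundays only
        f = forecast_visit(make_child(), D(2019, 7, 1), pakistan, cal)
        assert f.next_visit_date >= D(2019, 8, 12)
        assert f.next_visit_date.weekday() == 6


class TestRecordAdministration:
    def test_short_interval_warns_but_records(self, pakistan):
        # age floor for dose 2 (day 70) already met; only the gap is short
        child = make_child(doses=[("Penta", 1, "2019-08-20")])
        child, warnings = record_administration(
            child, "Penta", 2, D(2019, 9, 9), pakistan
        )  # 20-day gap, day 70 of life
        assert [w.kind for w in warnings] == [WarningKind.BELOW_MIN_INTERVAL]
        assert child.has("Penta", 2)

    def test_early_measles_warns_below_min_age(self, pakistan):
        child = make_child()
        _, warnings = record_administration(
            child, "Measles", 1, add_months(D(2019, 7, 1), 7), pakistan
        )
        assert [w.kind for w in warnings] == [WarningKind.BELOW_MIN_AGE]

    def test_conforming_dose_no_warnings(self, pakistan):
        _, warnings = record_administration(
            make_child(), "Penta", 1, D(2019, 8, 12), pakistan
        )
        assert warnings == []

    def test_late_bcg_warns_past_max_age(self, pakistan):
        _, warnings = record_administration(
            make_child(), "BCG", 1, D(2020, 8, 1), pakistan
        )
        assert [w.kind for w in warnings] == [WarningKind.PAST_MAX_AGE]

    def test_missing_prerequisite_warns(self, pakistan):
        _, warnings = record_administration(
            make_child(), "Penta", 2, D(2019, 10, 1), pakistan
        )
        assert WarningKind.MISSING_PREREQUISITE in {w.kind for w in warnings}

    def test_duplicate_is_hard_error(self, pakistan):
        child = make_child(doses=[("BCG", 1, "2019-07-01")])
        with pytest.raises(RecordError, match="already"):
            record_administration(child, "BCG", 1, D(2019, 7, 2), pakistan)


class TestReplay:
    def test_no_visits_empty(self, pakistan):
        assert replay(make_child(), [], pakistan) == []

    def test_history_accumulates_between_visits(self, pakistan):
        forecasts = replay(
            make_child(),
            [
                (D(2019, 7, 1), [("BCG", 1), ("OPV", 1)]),
                (D(2019, 8, 12), []),
            ],
            pakistan,
        )
        assert len(forecasts) == 2
        assert forecasts[0].due_now == {("BCG", 1), ("OPV", 1)}
        assert {("BCG", 1), ("OPV", 1)} <= forecasts[1].by_status(Status.GIVEN)
        assert forecasts[1].due_now == {
            ("Penta", 1), ("OPV", 2), ("PCV", 1), ("Rota", 1),
        }

    def test_delayed_first_contact_catchup(self, pakistan):
        [f] = replay(make_child(), [(add_months(D(2019, 7, 1), 6), [])], pakistan)
        assert f.due_now == {
            ("BCG", 1), ("Penta", 1), ("OPV", 2), ("PCV", 1), ("Rota", 1), ("IPV", 1),
        }
        statuses = {s.slot: s for s in f.statuses}
        assert statuses[("OPV", 1)].status is Status.NOT_INDICATED
        m1 = statuses[("Measles", 1)]
        assert m1.status is Status.SCHEDULED
        assert m1.scheduled_date == add_months(D(2019, 7, 1), 9)

    def test_unordered_visits_rejected(self, pakistan):
        with pytest.raises(ForecastError, match="chronological"):
            replay(make_child(), [(D(2019, 8, 1), []), (D(2019, 7, 1), [])], pakistan)


class TestForecastProperties:
    """Randomized invariants of the forecasting engine (seeded)."""

    COUNTRIES = ["pakistan_2019", "bangladesh_2019"]

    def _instances(self, schedule, n, seed):
        rng = np.random.default_rng(seed)
        return [random_child_and_visit(rng, schedule) for _ in range(n)]

    @pytest.mark.parametrize("country", COUNTRIES)
    def test_idempotence_after_administering_due_set(self, country, request):
        schedule = request.getfixturevalue(country.split("_")[0])
        for child, visit in self._instances(schedule, 200, seed=7):
            f = forecast_visit(child, visit, schedule)
            for slot in sorted(f.due_now):
                child, _ = record_administration(child, *slot, visit, schedule)
            assert forecast_visit(child, visit, schedule).due_now == set()

    @pytest.mark.parametrize("country", COUNTRIES)
    def test_monotonicity_adding_a_dose(self, country, request):
        schedule = request.getfixturevalue(country.split("_")[0])
        for child, visit in self._instances(schedule, 200, seed=8):
            f = forecast_visit(child, visit, schedule)
            given_before = f.by_status(Status.GIVEN)
            due_before = f.due_now
            if not due_before:
                continue
            slot = sorted(due_before)[0]
            child2, _ = record_administration(child, *slot, visit, schedule)
            f2 = forecast_visit(child2, visit, schedule)
            assert given_before <= f2.by_status(Status.GIVEN)
            # unrelated series keep their due dose
            for other in due_before:
                if other[0] != slot[0]:
                    assert other in f2.due_now

    @pytest.mark.parametrize("country", COUNTRIES)
    def test_scheduled_dates_follow_visit_and_series_order_holds(self, country, request):
        schedule = request.getfixturevalue(country.split("_")[0])
        for child, visit in self._instances(schedule, 300, seed=9):
            f = forecast_visit(child, visit, schedule)
            given = child.given_set()
            for s in f.statuses:
                if s.status is Status.SCHEDULED:
                    assert s.scheduled_date > visit
                if s.status is Status.DUE_NOW and schedule.rule(*s.slot).requires_previous:
                    assert (s.antigen, s.dose_index - 1) in given
            # at most one due dose per series
            for antigen, _ in schedule.series:
                assert sum(1 for sl in f.due_now if sl[0] == antigen) <= 1

    def test_calendar_safety(self, pakistan):
        cal = ServiceCalendar(
            service_weekdays=frozenset({0, 2, 4}),
            public_holidays=frozenset(
                {D(2019, 8, 12), D(2019, 9, 2), D(2019, 10, 7), D(2019, 12, 25)}
            ),
        )
        rng = np.random.default_rng(10)
        for _ in range(150):
            child, visit = random_child_and_visit(rng, pakistan)
            f = forecast_visit(child, visit, pakistan, cal)
            scheduled = [s for s in f.statuses if s.status is Status.SCHEDULED]
            if f.next_visit_date is not None:
                assert cal.serves(f.next_visit_date)
                assert f.next_visit_date >= min(s.scheduled_date for s in scheduled)

    @pytest.mark.parametrize("country", COUNTRIES)
    def test_randomized_concordance_with_gold_oracle(self, country, request):
        schedule = request.getfixturevalue(country.split("_")[0])
        rng = np.random.default_rng(11)
        for _ in range(1000):
            child, visit = random_child_and_visit(rng, schedule)
            assert forecast_visit(child, visit, schedule).due_now == gold_due(
                child, visit, country
            ), f"dob={child.dob} visit={visit} history={child.history}"
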