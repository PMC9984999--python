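"""The forecasting core: per-dose statuses, warnings, and next-visit dates.

Given a child's date of birth and dated history, :func:`forecast_visit`
assigns every dose slot of the active schedule one of four statuses —
``GIVEN``, ``DUE_NOW``, ``SCHEDULED`` (with the earliest feasible date) or
``NOT_INDICATED`` — and proposes a next-visit date rolled forward past
holidays and non-service days. The plan is recomputed from scratch at
every visit, which is what makes it a catch-up engine: a child who first
appears at 6 months simply gets the earliest feasible date for every
remaining dose, with within-series intervals chained off projected
administration dates.

Forecasting is deterministic and side-effect-free. Administration is
recorded with warnings but never blocked: off-schedule doses do happen in
the field, and the record must be able to represent them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from vaxcast._dates import age_on, parse_date
from vaxcast.records import ChildRecord, RecordError
from vaxcast.schedule import DoseRule, ScheduleDefinition, ServiceCalendar

__all__ = [
    "Status",
    "DoseStatus",
    "WarningKind",
    "Warning_",
    "VisitForecast",
    "age_on",
    "dose_status",
    "forecast_visit",
    "next_visit",
    "record_administration",
    "replay",
]


class Status(str, Enum):
    GIVEN = "GIVEN"
    DUE_NOW = "DUE_NOW"
    SCHEDULED = "SCHEDULED"
    NOT_INDICATED = "NOT_INDICATED"


class WarningKind(str, Enum):
    BELOW_MIN_AGE = "BELOW_MIN_AGE"
    BELOW_MIN_INTERVAL = "BELOW_MIN_INTERVAL"
    PAST_MAX_AGE = "PAST_MAX_AGE"
    MISSING_PREREQUISITE = "MISSING_PREREQUISITE"


@dataclass(frozen=True)
class Warning_:
    kind: WarningKind
    antigen: str
    dose_index: int
    detail: str


@dataclass(frozen=True)
class DoseStatus:
    antigen: str
    dose_index: int
    label: str
    status: Status
    scheduled_date: Optional[dt.date] = None
    basis: str = ""

    @property
    def slot(self) -> tuple[str, int]:
        return (self.antigen, self.dose_index)


@dataclass(frozen=True)
class VisitForecast:
    child_id: str
    visit_date: dt.date
    statuses: tuple[DoseStatus, ...]
    warnings: tuple[Warning_, ...] = ()
    next_visit_date: Optional[dt.date] = None

    def by_status(self, status: Status) -> set[tuple[str, int]]:
        return {s.slot for s in self.statuses if s.status == status}

    @property
    def due_now(self) -> set[tuple[str, int]]:
        return self.by_status(Status.DUE_NOW)

    def to_dict(self) -> dict:
        return {
            "child_id": self.child_id,
            "visit_date": self.visit_date.isoformat(),
            "statuses": [
                {
                    "antigen": s.antigen,
                    "dose_index": s.dose_index,
                    "label": s.label,
                    "status": s.status.value,
                    "scheduled_date": s.scheduled_date.isoformat()
                    if s.scheduled_date
                    else None,
                    "basis": s.basis,
                }
                for s in self.statuses
            ],
            "warnings": [
                {
                    "kind": w.kind.value,
                    "antigen": w.antigen,
                    "dose_index": w.dose_index,
                    "detail": w.detail,
                }
                for w in self.warnings
            ],
            "next_visit_date": self.next_visit_date.isoformat()
            if self.next_visit_date
            else None,
        }


class ForecastError(ValueError):
    """Invalid input to the forecasting engine."""


def _check_history_consistency(child: ChildRecord, schedule: ScheduleDefinition) -> None:
    """A chained dose on record without its prerequisite is a data error."""
    given = child.given_set()
    for rule in schedule.rules():
        if rule.requires_previous and rule.slot in given:
            if (rule.antigen, rule.dose_index - 1) not in given:
                raise ForecastError(
                    f"child {child.child_id}: {rule.label} recorded without "
                    f"{rule.antigen}-{rule.dose_index - 1}"
                )


def _series_statuses(
    child: ChildRecord,
    rules: Sequence[DoseRule],
    visit_date: dt.date,
) -> list[DoseStatus]:
    """Statuses for one antigen series, chaining intervals off projected dates.

    ``projected`` holds, per dose, the date it was (history), would be
    (due today), or is planned to be (scheduled) administered; a chained
    successor's earliest date is its prerequisite's projection plus the
    interval. Because a dose due today projects to the visit date, its
    successor lands at least one interval later — one dose per series per
    visit, structurally.
    """
    dob = child.dob
    out: list[DoseStatus] = []
    projected: dict[int, Optional[dt.date]] = {}
    for rule in rules:
        given_on = child.date_of(rule.antigen, rule.dose_index)
        if given_on is not None:
            projected[rule.dose_index] = given_on
            out.append(
                DoseStatus(*rule.slot, rule.label, Status.GIVEN, basis="in history")
            )
            continue

        cap = rule.max_age_date(dob)
        if cap is not None and visit_date > cap:
            projected[rule.dose_index] = None
            out.append(
                DoseStatus(
                    *rule.slot,
                    rule.label,
                    Status.NOT_INDICATED,
                    basis=f"past maximum age (last eligible day {cap.isoformat()})",
                )
            )
            continue

        earliest = rule.min_age_date(dob)
        basis = f"minimum age reached {earliest.isoformat()}"
        prereq_given = True
        if rule.requires_previous:
            prev = projected.get(rule.dose_index - 1)
            if prev is None:
                # prerequisite can never be administered (e.g. aged out)
                projected[rule.dose_index] = None
                out.append(
                    DoseStatus(
                        *rule.slot,
                        rule.label,
                        Status.NOT_INDICATED,
                        basis=f"prerequisite {rule.antigen}-{rule.dose_index - 1} "
                        "not attainable",
                    )
                )
                continue
            prereq_given = child.has(rule.antigen, rule.dose_index - 1)
            if rule.min_interval_days is not None:
                after = prev + dt.timedelta(days=rule.min_interval_days)
                if after > earliest:
                    earliest = after
                    basis = (
                        f"{rule.min_interval_days}-day interval after "
                        f"{rule.antigen}-{rule.dose_index - 1} ({prev.isoformat()})"
                    )
        if cap is not None and earliest > cap:
            projected[rule.dose_index] = None
            out.append(
                DoseStatus(
                    *rule.slot,
                    rule.label,
                    Status.NOT_INDICATED,
                    basis=f"earliest feasible date {earliest.isoformat()} past cap "
                    f"{cap.isoformat()}",
                )
            )
            continue
        if earliest <= visit_date and prereq_given:
            projected[rule.dose_index] = visit_date
            out.append(DoseStatus(*rule.slot, rule.label, Status.DUE_NOW, basis=basis))
        else:
            when = max(earliest, visit_date + dt.timedelta(days=1))
            projected[rule.dose_index] = when
            out.append(
                DoseStatus(
                    *rule.slot,
                    rule.label,
                    Status.SCHEDULED,
                    scheduled_date=when,
                    basis=basis,
                )
            )
    return out


def dose_status(
    child: ChildRecord,
    rule: DoseRule,
    visit_date,
    schedule: ScheduleDefinition,
) -> DoseStatus:
    """Status of a single dose slot at ``visit_date``.

    The rule is evaluated in the context of its series (chained intervals
    need the prerequisite's actual or projected date).
    """
    visit_date = parse_date(visit_date)
    rules = schedule.series_rules(rule.antigen)
    _check_history_consistency(child, schedule)
    statuses = _series_statuses(child, rules, visit_date)
    return statuses[rule.dose_index - 1]


def next_visit(
    pending: Iterable[DoseStatus],
    calendar: Optional[ServiceCalendar],
) -> Optional[dt.date]:
    """Proposed next-visit date for the earliest scheduled dose(s).

    The earliest scheduled eligibility date is advanced to the first day
    that is a service weekday, not a public holiday, and — when per-antigen
    service days are configured — a day on which at least one of the
    earliest-due antigens is offered. Never moves a date backward.
    """
    scheduled = [s for s in pending if s.status == Status.SCHEDULED]
    if not scheduled:
        return None
    d0 = min(s.scheduled_date for s in scheduled)
    if calendar is None:
        return d0
    antigens = {s.antigen for s in scheduled if s.scheduled_date == d0}
    candidates = [calendar.next_service_day(d0, a) for a in antigens]
    return min(candidates)


def forecast_visit(
    child: ChildRecord,
    visit_date,
    schedule: ScheduleDefinition,
    calendar: Optional[ServiceCalendar] = None,
) -> VisitForecast:
    """Full per-slot forecast for one visit, with a proposed next-visit date."""
    visit_date = parse_date(visit_date)
    if visit_date < child.dob:
        raise ForecastError(
            f"visit date {visit_date} precedes date of birth {child.dob}"
        )
    if not list(schedule.rules()):
        raise ForecastError("empty schedule")
    _check_history_consistency(child, schedule)
    if calendar is None:
        calendar = schedule.calendar
    statuses: list[DoseStatus] = []
    for _, rules in schedule.series:
        statuses.extend(_series_statuses(child, rules, visit_date))
    return VisitForecast(
        child_id=child.child_id,
        visit_date=visit_date,
        statuses=tuple(statuses),
        warnings=(),
        next_visit_date=next_visit(statuses, calendar),
    )


def record_administration(
    child: ChildRecord,
    antigen: str,
    dose_index: int,
    date,
    schedule: ScheduleDefinition,
) -> tuple[ChildRecord, list[Warning_]]:
    """Record a dose, emitting rule-violation warnings but never blocking.

    Duplicate doses and dates before birth are hard errors (they corrupt
    the record); everything else — below minimum age, below minimum
    interval, past the age cap, missing prerequisite — is a warning, and
    the administration is recorded regardless.
    """
    date = parse_date(date)
    if child.has(antigen, dose_index):
        raise RecordError(f"{antigen}-{dose_index} already recorded")
    rule = schedule.rule(antigen, dose_index)
    warnings: list[Warning_] = []

    def warn(kind: WarningKind, detail: str):
        warnings.append(Warning_(kind, antigen, dose_index, detail))

    if date < rule.min_age_date(child.dob):
        warn(
            WarningKind.BELOW_MIN_AGE,
            f"administered {date.isoformat()}, minimum-age date "
            f"{rule.min_age_date(child.dob).isoformat()}",
        )
    cap = rule.max_age_date(child.dob)
    if cap is not None and date > cap:
        warn(WarningKind.PAST_MAX_AGE, f"last eligible day was {cap.isoformat()}")
    if rule.requires_previous:
        prev = child.date_of(antigen, dose_index - 1)
        if prev is None:
            warn(
                WarningKind.MISSING_PREREQUISITE,
                f"{antigen}-{dose_index - 1} not on record",
            )
        elif rule.min_interval_days is not None:
            gap = (date - prev).days
            if gap < rule.min_interval_days:
                warn(
                    WarningKind.BELOW_MIN_INTERVAL,
                    f"{gap} days since {antigen}-{dose_index - 1}, minimum "
                    f"{rule.min_interval_days}",
                )
    updated = child.with_dose(antigen, dose_index, date)  # raises if date < dob
    return updated, warnings


def replay(
    child: ChildRecord,
    visits: Sequence[tuple[object, Iterable[tuple[str, int]]]],
    schedule: ScheduleDefinition,
    calendar: Optional[ServiceCalendar] = None,
) -> list[VisitForecast]:
    """Forecast a chronological visit sequence with history accumulating.

    Each element of ``visits`` is ``(visit_date, administered_slots)``;
    the forecast at a visit reflects history from *earlier* visits only,
    then that visit's administrations are recorded.
    """
    dates = [parse_date(d) for d, _ in visits]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ForecastError("visits must be in chronological order")
    out: list[VisitForecast] = []
    current = child
    for visit_date, administered in visits:
        out.append(forecast_visit(current, visit_date, schedule, calendar))
        for antigen, dose_index in administered:
            current, _ = record_administration(
                current, antigen, dose_index, visit_date, schedule
            )
    return out
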