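"""EPI schedule definitions and service calendars.

A schedule is a set of antigen series, each an ordered list of per-dose
eligibility rules: minimum age, minimum interval since the previous dose
of the same series, and an optional maximum-age ceiling (e.g. the birth
OPV dose is only indicated through day 28). Prerequisites are strictly
within-series — a dose of one antigen never depends on another antigen's
series. That structural choice is deliberate: the classic vaccinator error
is tying the 14-week IPV dose or the 9-month measles dose to pentavalent
progress, and the engine must be incapable of reproducing it.

Age thresholds quoted in weeks are stored as exact day counts (6 w = 42 d);
thresholds quoted in months or years are kept in calendar units and
resolved against each child's date of birth by calendar addition with
end-of-month clamping. Interval rules of the form "more than 28 days
after" are stored as ``min_interval_days = 29`` (strict inequality);
"through 28 days of age" is ``max_age_days = 28`` inclusive.

Two national 2019 schedules ship with the package (``pakistan_2019``,
``bangladesh_2019``) as YAML files under ``vaxcast/data``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import yaml

from vaxcast._dates import add_months, add_years, parse_date

BUILTIN_IDS = ("pakistan_2019", "bangladesh_2019")

WEEKDAY_NAMES = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]


class ScheduleError(ValueError):
    """A schedule or calendar definition violates its schema/invariants."""


@dataclass(frozen=True)
class DoseRule:
    """Eligibility rule for one dose slot of an antigen series.

    Exactly one of ``min_age_days`` / ``min_age_months`` is set; at most
    one of ``max_age_days`` / ``max_age_years``. ``requires_previous``
    marks the previous dose of the *same* series as a prerequisite, and
    ``min_interval_days`` is counted from that dose's administration date.
    """

    antigen: str
    dose_index: int
    label: str
    min_age_days: Optional[int] = None
    min_age_months: Optional[int] = None
    min_interval_days: Optional[int] = None
    max_age_days: Optional[int] = None
    max_age_years: Optional[int] = None
    requires_previous: bool = False

    def __post_init__(self):
        if (self.min_age_days is None) == (self.min_age_months is None):
            raise ScheduleError(
                f"{self.label}: exactly one of min_age_days/min_age_months required"
            )
        if self.max_age_days is not None and self.max_age_years is not None:
            raise ScheduleError(f"{self.label}: max_age_days and max_age_years both set")
        if self.dose_index < 1:
            raise ScheduleError(f"{self.label}: dose_index must be >= 1")
        if self.min_interval_days is not None and not self.requires_previous:
            raise ScheduleError(
                f"{self.label}: min_interval_days without requires_previous"
            )

    @property
    def slot(self) -> tuple[str, int]:
        return (self.antigen, self.dose_index)

    def min_age_date(self, dob: dt.date) -> dt.date:
        """Earliest date the child meets this rule's age floor."""
        if self.min_age_days is not None:
            return dob + dt.timedelta(days=self.min_age_days)
        return add_months(dob, self.min_age_months)

    def max_age_date(self, dob: dt.date) -> Optional[dt.date]:
        """Last date (inclusive) the dose is still indicated, if capped."""
        if self.max_age_days is not None:
            return dob + dt.timedelta(days=self.max_age_days)
        if self.max_age_years is not None:
            return add_years(dob, self.max_age_years)
        return None

    def _nominal_min_age_days(self) -> int:
        # for schema validation only; calendar months approximated
        if self.min_age_days is not None:
            return self.min_age_days
        return round(self.min_age_months * 30.44)


@dataclass(frozen=True)
class ServiceCalendar:
    """Which days a center actually vaccinates.

    ``service_weekdays`` uses Python weekday numbers (0 = Monday). When
    ``antigen_days`` names an antigen, that antigen is only offered on the
    listed subset of service days (some centers batch e.g. BCG sessions).
    """

    service_weekdays: frozenset[int] = frozenset(range(7))
    public_holidays: frozenset[dt.date] = frozenset()
    antigen_days: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "service_weekdays", frozenset(self.service_weekdays))
        object.__setattr__(
            self, "public_holidays", frozenset(parse_date(d) for d in self.public_holidays)
        )
        object.__setattr__(
            self,
            "antigen_days",
            {a: frozenset(ds) for a, ds in dict(self.antigen_days).items()},
        )
        if not self.service_weekdays:
            raise ScheduleError("calendar: service_weekdays must be non-empty")
        for antigen, days in self.antigen_days.items():
            if not days <= self.service_weekdays:
                raise ScheduleError(
                    f"calendar: {antigen} days {sorted(days)} not a subset of "
                    f"service weekdays {sorted(self.service_weekdays)}"
                )

    def serves(self, day: dt.date, antigen: Optional[str] = None) -> bool:
        if day.weekday() not in self.service_weekdays or day in self.public_holidays:
            return False
        if antigen is not None and antigen in self.antigen_days:
            return day.weekday() in self.antigen_days[antigen]
        return True

    def next_service_day(self, day: dt.date, antigen: Optional[str] = None) -> dt.date:
        """First date >= ``day`` on which ``antigen`` (or anything) is offered."""
        d = day
        for _ in range(4000):  # bounded scan; a non-empty weekday set terminates fast
            if self.serves(d, antigen):
                return d
            d += dt.timedelta(days=1)
        raise ScheduleError("calendar: no service day found within bounded scan")


@dataclass(frozen=True)
class ScheduleDefinition:
    """A country's full antigen-series rule set plus co-administration groups."""

    country_id: str
    series: tuple[tuple[str, tuple[DoseRule, ...]], ...]
    coadmin_groups: tuple[frozenset[tuple[str, int]], ...] = ()
    calendar: Optional[ServiceCalendar] = None

    def __post_init__(self):
        object.__setattr__(
            self,
            "series",
            tuple((a, tuple(rules)) for a, rules in self.series),
        )
        object.__setattr__(
            self,
            "coadmin_groups",
            tuple(frozenset(tuple(m) for m in g) for g in self.coadmin_groups),
        )
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        for antigen, rules in self.series:
            if not rules:
                raise ScheduleError(f"{self.country_id}: empty series {antigen}")
            prev_age = -1
            for i, rule in enumerate(rules, start=1):
                if rule.antigen != antigen:
                    raise ScheduleError(
                        f"{self.country_id}: rule {rule.label} filed under series {antigen}"
                    )
                if rule.dose_index != i:
                    raise ScheduleError(
                        f"{self.country_id}: {antigen} dose_index not consecutive from 1 "
                        f"(got {rule.dose_index} at position {i})"
                    )
                if rule.slot in seen:
                    raise ScheduleError(f"{self.country_id}: duplicate slot {rule.slot}")
                seen.add(rule.slot)
                age = rule._nominal_min_age_days()
                if age < prev_age:
                    raise ScheduleError(
                        f"{self.country_id}: {antigen} min ages not non-decreasing"
                    )
                prev_age = age
        for group in self.coadmin_groups:
            unknown = group - seen
            if unknown:
                raise ScheduleError(
                    f"{self.country_id}: coadmin group references unknown slots {sorted(unknown)}"
                )
            ages = {
                (r.min_age_days, r.min_age_months)
                for r in self.rules()
                if r.slot in group
            }
            if len(ages) != 1:
                raise ScheduleError(
                    f"{self.country_id}: coadmin group {sorted(group)} mixes minimum ages"
                )

    # -- lookups --------------------------------------------------------
    def rules(self) -> Iterable[DoseRule]:
        for _, rules in self.series:
            yield from rules

    def series_rules(self, antigen: str) -> tuple[DoseRule, ...]:
        for a, rules in self.series:
            if a == antigen:
                return rules
        raise KeyError(antigen)

    def rule(self, antigen: str, dose_index: int) -> DoseRule:
        rules = self.series_rules(antigen)
        if not 1 <= dose_index <= len(rules):
            raise KeyError((antigen, dose_index))
        return rules[dose_index - 1]

    @property
    def slots(self) -> list[tuple[str, int]]:
        return [r.slot for r in self.rules()]

    def label(self, antigen: str, dose_index: int) -> str:
        return self.rule(antigen, dose_index).label


# -- parsing / serialization -------------------------------------------


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ScheduleError(f"{where}: missing required field '{key}'")
    return mapping[key]


def _opt_int(mapping: dict, key: str, where: str) -> Optional[int]:
    value = mapping.get(key)
    if value is None:
        return None
    if not isinstance(value, int) or isinstance(value, bool) or value < 0:
        raise ScheduleError(f"{where}: field '{key}' must be a non-negative integer")
    return value


def _parse_calendar(data: dict) -> ServiceCalendar:
    if not isinstance(data, dict):
        raise ScheduleError("calendar: expected a mapping")
    weekday_map = {name: i for i, name in enumerate(WEEKDAY_NAMES)}

    def to_weekdays(values, where):
        days = set()
        for v in values:
            if isinstance(v, int) and 0 <= v <= 6:
                days.add(v)
            elif isinstance(v, str) and v.lower()[:3] in weekday_map:
                days.add(weekday_map[v.lower()[:3]])
            else:
                raise ScheduleError(f"{where}: unrecognised weekday {v!r}")
        return frozenset(days)

    return ServiceCalendar(
        service_weekdays=to_weekdays(
            data.get("service_weekdays", list(range(7))), "calendar.service_weekdays"
        ),
        public_holidays=frozenset(
            parse_date(d) for d in data.get("public_holidays", [])
        ),
        antigen_days={
            a: to_weekdays(ds, f"calendar.antigen_days.{a}")
            for a, ds in (data.get("antigen_days") or {}).items()
        },
    )


def _schedule_from_dict(data: dict) -> ScheduleDefinition:
    if not isinstance(data, dict):
        raise ScheduleError("schedule: top level must be a mapping")
    country_id = _require(data, "country_id", "schedule")
    series_cfg = _require(data, "series", "schedule")
    if not isinstance(series_cfg, list) or not series_cfg:
        raise ScheduleError("schedule: 'series' must be a non-empty list")
    series = []
    for s in series_cfg:
        antigen = _require(s, "antigen", "series entry")
        doses_cfg = _require(s, "doses", f"series {antigen}")
        rules = []
        for d in doses_cfg:
            where = f"{antigen} dose {d.get('index', '?')}"
            rules.append(
                DoseRule(
                    antigen=antigen,
                    dose_index=_require(d, "index", where),
                    label=d.get("label", f"{antigen}-{d.get('index')}"),
                    min_age_days=_opt_int(d, "min_age_days", where),
                    min_age_months=_opt_int(d, "min_age_months", where),
                    min_interval_days=_opt_int(d, "min_interval_days", where),
                    max_age_days=_opt_int(d, "max_age_days", where),
                    max_age_years=_opt_int(d, "max_age_years", where),
                    requires_previous=bool(d.get("requires_previous", False)),
                )
            )
        series.append((antigen, tuple(rules)))
    groups = tuple(
        frozenset((m[0], int(m[1])) for m in g) for g in data.get("coadmin_groups", [])
    )
    calendar = _parse_calendar(data["calendar"]) if data.get("calendar") else None
    return ScheduleDefinition(
        country_id=country_id, series=tuple(series), coadmin_groups=groups, calendar=calendar
    )


def load_schedule(config_text: str) -> ScheduleDefinition:
    """Parse and validate a schedule definition from YAML or JSON text."""
    try:
        data = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ScheduleError(f"schedule: config does not parse: {exc}") from exc
    return _schedule_from_dict(data)


def serialize_schedule(schedule: ScheduleDefinition) -> str:
    """YAML text that :func:`load_schedule` parses back to an equal schedule."""
    data: dict = {"country_id": schedule.country_id, "series": []}
    for antigen, rules in schedule.series:
        doses = []
        for r in rules:
            d: dict = {"index": r.dose_index, "label": r.label}
            for k in (
                "min_age_days",
                "min_age_months",
                "min_interval_days",
                "max_age_days",
                "max_age_years",
            ):
                v = getattr(r, k)
                if v is not None:
                    d[k] = v
            if r.requires_previous:
                d["requires_previous"] = True
            doses.append(d)
        data["series"].append({"antigen": antigen, "doses": doses})
    if schedule.coadmin_groups:
        data["coadmin_groups"] = [
            sorted([a, i] for a, i in g) for g in schedule.coadmin_groups
        ]
    if schedule.calendar is not None:
        cal = schedule.calendar
        data["calendar"] = {
            "service_weekdays": sorted(cal.service_weekdays),
            "public_holidays": sorted(d.isoformat() for d in cal.public_holidays),
            "antigen_days": {a: sorted(ds) for a, ds in sorted(cal.antigen_days.items())},
        }
    return yaml.safe_dump(data, sort_keys=False)


def builtin_schedule(country_id: str) -> ScheduleDefinition:
    """One of the packaged national schedules (``pakistan_2019``, ``bangladesh_2019``)."""
    if country_id not in BUILTIN_IDS:
        raise ScheduleError(
            f"unknown schedule id {country_id!r}; available: {', '.join(BUILTIN_IDS)}"
        )
    text = resources.files("vaxcast").joinpath(f"data/{country_id}.yaml").read_text()
    return load_schedule(text)
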