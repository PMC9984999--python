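"""Synthetic immunization cohorts with a parameterised vaccinator-error model.

The generator emulates the registry data of a two-country MOV field study:
children born over a window, attending milestone visits (birth, 6/10/14
weeks, 9 and 15 months) with right-skewed delays, entering observation at
an enrollment age drawn from the study's enrollment-age mix. At every
observed visit three things are recorded for the same child simultaneously:
the gold-standard due set, the forecast engine's DUE_NOW set, and the set a
simulated vaccinator actually administers.

The vaccinator starts from the gold-standard due set and applies, with
configured probabilities, the documented field error behaviours:

* ``p_ipv_tied_to_penta3`` — the belief that the 14-week IPV dose must be
  co-administered with Penta-3, so IPV is withheld whenever Penta-3 is
  neither given at this visit nor already on record;
* ``p_measles_locked_on_penta3`` — measles dose 1 "locked" until the
  child has received Penta-3;
* ``p_calendar_month_interval`` — the next chained dose scheduled at
  "+1 calendar month" instead of the 29th day, so a dose whose 29-day
  interval has elapsed but whose calendar month has not is deferred;
* ``p_weekend_unadjusted`` — next-visit dates copied onto non-service
  days, arriving as extra visit delay (it alters timing, not the set);
* ``p_random_miss`` — an unstructured per-dose omission.

Everything is driven by one seeded generator: the same config and seed
reproduce the output byte for byte.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from dateutil.relativedelta import relativedelta

from vaxcast._dates import add_months, parse_date
from vaxcast.engine import forecast_visit
from vaxcast.evaluation import (
    ConfusionCounts,
    DiagStats,
    MovRate,
    StudyRow,
    StudyTable,
    aggregate_table,
    confusion_from_records,
    diag_stats,
    mov_rate,
)
from vaxcast.gold import gold_due
from vaxcast.records import ChildRecord, write_records_csv
from vaxcast.schedule import ScheduleDefinition, builtin_schedule

Slot = tuple[str, int]

#: Enrollment-age mix over {<=6, 6-12, 12-18, 18-24} months, as observed
#: across both study sites (72.6 / 15.1 / 11.4 / 0.9 percent).
DEFAULT_ENROLLMENT_MIX = {
    "0-6m": 0.726,
    "6-12m": 0.151,
    "12-18m": 0.114,
    "18-24m": 0.009,
}

_MIX_BIN_DAYS = {
    "0-6m": (0, 183),
    "6-12m": (183, 366),
    "12-18m": (366, 548),
    "18-24m": (548, 731),
}

#: Per-milestone visit delay (mean, SD) in days, gamma-distributed.
#: Derived from the study cohort's mean (SD) ages at each enrollment
#: vaccine — e.g. first pentavalent dose at 8.8 (5.2) weeks against a
#: 6-week target gives a mean delay of ~2.8 weeks — so the simulated
#: timeliness matches the field distribution in mean and spread.
DEFAULT_VISIT_DELAYS = {
    "birth": (22.4, 25.9),
    "6w": (19.6, 36.4),
    "10w": (30.8, 38.5),
    "14w": (44.8, 53.9),
    "9m": (18.0, 47.6),
    "15m": (18.9, 42.0),
}

_MILESTONE_TARGET_DAYS = {"birth": 0, "6w": 42, "10w": 70, "14w": 98}
_MILESTONE_TARGET_MONTHS = {"9m": 9, "15m": 15}
_MILESTONES = ["birth", "6w", "10w", "14w", "9m", "15m"]


class SimError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ErrorModel:
    """Per-visit probabilities of the documented vaccinator error behaviours."""

    p_ipv_tied_to_penta3: float = 0.0
    p_measles_locked_on_penta3: float = 0.0
    p_calendar_month_interval: float = 0.0
    p_weekend_unadjusted: float = 0.0
    p_random_miss: float = 0.0

    def __post_init__(self):
        for name in (
            "p_ipv_tied_to_penta3",
            "p_measles_locked_on_penta3",
            "p_calendar_month_interval",
            "p_weekend_unadjusted",
            "p_random_miss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimError(f"{name}={v} outside [0, 1]")

    @property
    def error_free(self) -> bool:
        return (
            self.p_ipv_tied_to_penta3
            == self.p_measles_locked_on_penta3
            == self.p_calendar_month_interval
            == self.p_weekend_unadjusted
            == self.p_random_miss
            == 0.0
        )


@dataclass(frozen=True)
class SimConfig:
    n_children: int = 500
    country_id: str = "pakistan_2019"
    dob_start: dt.date = dt.date(2019, 1, 1)
    dob_end: dt.date = dt.date(2019, 12, 31)
    enrollment_age_mix: dict = field(default_factory=lambda: dict(DEFAULT_ENROLLMENT_MIX))
    visit_delays: dict = field(default_factory=lambda: dict(DEFAULT_VISIT_DELAYS))
    attendance_prob: float = 0.9
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "dob_start", parse_date(self.dob_start))
        object.__setattr__(self, "dob_end", parse_date(self.dob_end))
        if self.n_children < 1:
            raise SimError("n_children must be >= 1")
        if self.dob_end < self.dob_start:
            raise SimError("dob_end precedes dob_start")
        if set(self.enrollment_age_mix) - set(_MIX_BIN_DAYS):
            raise SimError(
                f"unknown enrollment bins {set(self.enrollment_age_mix) - set(_MIX_BIN_DAYS)}"
            )
        total = sum(self.enrollment_age_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SimError(f"enrollment_age_mix sums to {total}, expected 1")
        for name, (mean, sd) in self.visit_delays.items():
            if name not in _MILESTONES:
                raise SimError(f"unknown milestone {name!r}")
            if mean < 0 or sd < 0:
                raise SimError(f"milestone {name}: delay mean/SD must be >= 0")
        if not 0.0 <= self.attendance_prob <= 1.0:
            raise SimError("attendance_prob outside [0, 1]")


@dataclass(frozen=True)
class VisitObs:
    """One observed visit: the three schedules captured simultaneously."""

    child_id: str
    visit_date: dt.date
    gold: tuple[Slot, ...]
    engine: tuple[Slot, ...]
    vaccinator: tuple[Slot, ...]
    given_before: tuple[Slot, ...]

    def to_dict(self) -> dict:
        return {
            "child_id": self.child_id,
            "visit_date": self.visit_date.isoformat(),
            "gold": [list(s) for s in self.gold],
            "engine": [list(s) for s in self.engine],
            "vaccinator": [list(s) for s in self.vaccinator],
            "given_before": [list(s) for s in self.given_before],
        }


@dataclass(frozen=True)
class SimOutput:
    config: SimConfig
    errors: ErrorModel
    children: tuple[ChildRecord, ...]
    visits: tuple[VisitObs, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "country_id": self.config.country_id,
                "seed": self.config.seed,
                "n_children": self.config.n_children,
                "visits": [v.to_dict() for v in self.visits],
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_records_csv(self.children, outdir / "records.csv")
        (outdir / "visits.json").write_text(self.to_json())


def _milestone_date(dob: dt.date, name: str) -> dt.date:
    if name in _MILESTONE_TARGET_DAYS:
        return dob + dt.timedelta(days=_MILESTONE_TARGET_DAYS[name])
    return add_months(dob, _MILESTONE_TARGET_MONTHS[name])


def _sample_delay(rng: np.random.Generator, mean: float, sd: float) -> int:
    if mean <= 0:
        return 0
    if sd <= 0:
        return int(round(mean))
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return int(round(rng.gamma(shape, scale)))


def vaccinator_behavior(
    due: set[Slot],
    child: ChildRecord,
    visit_date: dt.date,
    err: ErrorModel,
    rng: np.random.Generator,
    country_id: str,
) -> set[Slot]:
    """The set a simulated vaccinator administers, starting from the due set.

    Only removes doses (the gold standard already excludes anything past
    its age ceiling, so nothing inadmissible can be added).
    """
    admin = set(due)
    ipv_slot: Slot = ("IPV", 1) if country_id == "pakistan_2019" else ("IPV", 2)
    measles1: Slot = (
        ("Measles", 1) if country_id == "pakistan_2019" else ("MR", 1)
    )

    # "+1 calendar month" scheduling: a chained dose whose 29-day interval
    # has elapsed but whose calendar month since the previous dose has not
    if err.p_calendar_month_interval > 0:
        for antigen, idx in sorted(due):
            if idx < 2:
                continue
            prev = child.date_of(antigen, idx - 1)
            if prev is None:
                continue  # dose not interval-chained to history (e.g. 14-week IPV)
            if visit_date < prev + relativedelta(months=1):
                if rng.random() < err.p_calendar_month_interval:
                    admin.discard((antigen, idx))

    if err.p_random_miss > 0:
        for slot in sorted(admin):
            if rng.random() < err.p_random_miss:
                admin.discard(slot)

    penta3_seen = ("Penta", 3) in admin or child.has("Penta", 3)
    if ipv_slot in admin and not penta3_seen:
        if rng.random() < err.p_ipv_tied_to_penta3:
            admin.discard(ipv_slot)
    if measles1 in admin and not penta3_seen:
        if rng.random() < err.p_measles_locked_on_penta3:
            admin.discard(measles1)
    return admin


def simulate_cohort(cfg: SimConfig, err: Optional[ErrorModel] = None) -> SimOutput:
    """Generate a cohort and capture gold/engine/vaccinator sets per visit.

    Visits before the child's enrollment age form the card history and are
    administered exactly per the gold standard; visits from enrollment
    onward are observed, and the error model shapes what the vaccinator
    gives. Administered doses (vaccinator's choices) accumulate into the
    record, so errors propagate to later visits just as they do on a real
    immunization card. A child whose milestone visits all precede
    enrollment still contributes one catch-up visit at the enrollment age.
    """
    err = err or ErrorModel()
    schedule = builtin_schedule(cfg.country_id)
    rng = np.random.default_rng(cfg.seed)
    window = (cfg.dob_end - cfg.dob_start).days + 1
    bins = sorted(cfg.enrollment_age_mix)
    probs = np.array([cfg.enrollment_age_mix[b] for b in bins])

    children: list[ChildRecord] = []
    observations: list[VisitObs] = []
    for i in range(cfg.n_children):
        dob = cfg.dob_start + dt.timedelta(days=int(rng.integers(0, window)))
        child = ChildRecord(child_id=f"sim{i:05d}", dob=dob)

        bin_name = bins[int(rng.choice(len(bins), p=probs))]
        lo, hi = _MIX_BIN_DAYS[bin_name]
        enroll_age = int(rng.integers(lo, hi))

        visit_dates: list[dt.date] = []
        prev: Optional[dt.date] = None
        for name in _MILESTONES:
            if cfg.country_id == "bangladesh_2019" and name == "birth":
                # Bangladesh's only birth antigen (BCG) is routinely given
                # at the first EPI contact; keep the birth visit anyway so
                # both countries share a trajectory shape
                pass
            mean, sd = cfg.visit_delays.get(name, (0.0, 0.0))
            date = _milestone_date(dob, name) + dt.timedelta(
                days=_sample_delay(rng, mean, sd)
            )
            if prev is not None and date <= prev:
                date = prev + dt.timedelta(days=1)
            attended = rng.random() < cfg.attendance_prob
            prev = date
            if attended:
                visit_dates.append(date)

        enroll_date = dob + dt.timedelta(days=enroll_age)
        if not any(d >= enroll_date for d in visit_dates):
            visit_dates.append(enroll_date)

        last: Optional[dt.date] = None
        for date in visit_dates:
            if date < enroll_date:
                if last is not None and date <= last:
                    date = last + dt.timedelta(days=1)
                last = date
                # pre-enrollment: card history, administered per gold standard
                for slot in sorted(gold_due(child, date, cfg.country_id)):
                    child = child.with_dose(*slot, date)
                continue
            if err.p_weekend_unadjusted > 0 and rng.random() < err.p_weekend_unadjusted:
                # schedule landed on a closed day; family returns later
                date = date + dt.timedelta(days=int(rng.integers(1, 3)))
            if last is not None and date <= last:
                date = last + dt.timedelta(days=1)
            last = date
            gold = gold_due(child, date, cfg.country_id)
            engine = forecast_visit(child, date, schedule).due_now
            vacc = vaccinator_behavior(gold, child, date, err, rng, cfg.country_id)
            observations.append(
                VisitObs(
                    child_id=child.child_id,
                    visit_date=date,
                    gold=tuple(sorted(gold)),
                    engine=tuple(sorted(engine)),
                    vaccinator=tuple(sorted(vacc)),
                    given_before=tuple(sorted(child.given_set())),
                )
            )
            for slot in sorted(vacc):
                child = child.with_dose(*slot, date)
        children.append(child)

    return SimOutput(
        config=cfg, errors=err, children=tuple(children), visits=tuple(observations)
    )


# -- study-shaped reporting --------------------------------------------


def report_label(country_id: str, antigen: str, dose_index: int) -> str:
    """Study-table row label for a slot (OPV numbering and the 14-week IPV
    dose follow the table's conventions; measles and MR share ``M-k``)."""
    if antigen == "BCG":
        return "BCG"
    if country_id == "pakistan_2019":
        if antigen == "OPV":
            return f"OPV-{dose_index - 1}"
        if antigen == "IPV":
            return "IPV-2"
        if antigen == "Measles":
            return f"M-{dose_index}"
    else:
        if antigen == "MR":
            return f"M-{dose_index}"
    return f"{antigen}-{dose_index}"


@dataclass(frozen=True)
class StudyReport:
    table: StudyTable
    engine_stats: dict
    vaccinator_stats: dict
    mov_overall: MovRate
    engine_concordance_pct: float


def run_study(sim: SimOutput, site: Optional[str] = None) -> StudyReport:
    """Study-table-shaped report for engine-vs-gold and vaccinator-vs-gold."""
    if not sim.visits:
        raise SimError("simulation produced no observed visits")
    country = sim.config.country_id
    site = site or country.split("_")[0]
    schedule: ScheduleDefinition = builtin_schedule(country)
    slots = schedule.slots

    gold = {(v.child_id, v.visit_date): set(v.gold) for v in sim.visits}
    engine = {(v.child_id, v.visit_date): set(v.engine) for v in sim.visits}
    vacc = {(v.child_id, v.visit_date): set(v.vaccinator) for v in sim.visits}

    conf_engine = confusion_from_records(gold, engine, site=site, slots=slots)
    conf_vacc = confusion_from_records(gold, vacc, site=site, slots=slots)

    rows = []
    engine_stats: dict[str, DiagStats] = {}
    vacc_stats: dict[str, DiagStats] = {}
    for ce, cv in zip(conf_engine, conf_vacc):
        label = report_label(country, ce.antigen, ce.dose_index)
        if ce.tp + ce.fn == 0:
            continue  # slot never due in this cohort; no study row
        rows.append(
            StudyRow(
                site=site,
                label=label,
                due_gold=ce.tp + ce.fn,
                idss_yes=ce.tp,
                idss_no=ce.fn,
                vacc_yes=cv.tp,
                vacc_no=cv.fn,
            )
        )
        engine_stats[label] = diag_stats(ce)
        vacc_stats[label] = diag_stats(cv)

    table = aggregate_table(rows)
    total = table.site_totals[site]
    agree = sum(1 for v in sim.visits if v.gold == v.engine)
    return StudyReport(
        table=table,
        engine_stats=engine_stats,
        vaccinator_stats=vacc_stats,
        mov_overall=mov_rate(total.due_gold, total.vacc_no),
        engine_concordance_pct=100.0 * agree / len(sim.visits),
    )


def component_rates(sim: SimOutput) -> dict[str, tuple[int, int]]:
    """Realized (opportunities, misses) per error mechanism.

    An *opportunity* is a visit-dose at which the mechanism could have
    fired: IPV due without Penta-3 at hand for the IPV tie; measles-1 due
    without Penta-3 on record for the measles lock; a chained due dose
    inside the "+1 calendar month" window for the interval error; and any
    due dose for the unstructured miss. Dividing misses by opportunities
    recovers the configured probability when a single knob is active.
    """
    country = sim.config.country_id
    ipv_slot: Slot = ("IPV", 1) if country == "pakistan_2019" else ("IPV", 2)
    measles1: Slot = ("Measles", 1) if country == "pakistan_2019" else ("MR", 1)
    by_child = {c.child_id: c for c in sim.children}

    out = {
        "random_miss": [0, 0],
        "ipv_tie": [0, 0],
        "measles_lock": [0, 0],
        "calendar_month": [0, 0],
    }
    for v in sim.visits:
        gold, vacc, before = set(v.gold), set(v.vaccinator), set(v.given_before)
        out["random_miss"][0] += len(gold)
        out["random_miss"][1] += len(gold - vacc)
        if ipv_slot in gold and ("Penta", 3) not in (vacc | before):
            out["ipv_tie"][0] += 1
            out["ipv_tie"][1] += ipv_slot not in vacc
        if measles1 in gold and ("Penta", 3) not in (vacc | before):
            out["measles_lock"][0] += 1
            out["measles_lock"][1] += measles1 not in vacc
        child = by_child[v.child_id]
        for antigen, idx in gold:
            if idx < 2:
                continue
            prev = child.date_of(antigen, idx - 1)
            if prev is not None and prev < v.visit_date < prev + relativedelta(months=1):
                out["calendar_month"][0] += 1
                out["calendar_month"][1] += (antigen, idx) not in vacc
    return {k: (n, m) for k, (n, m) in out.items()}
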