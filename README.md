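# vaxcast

Immunization schedule forecasting, missed-opportunity evaluation and
cohort simulation for Expanded Programme on Immunization (EPI) settings.

## The problem

When a child visits an immunization center, the vaccinator must work out,
from the date of birth and the card history, which doses are due *today*
and when the next visit should be. For a child who is behind schedule this
is a genuinely hard catch-up calculation — minimum ages, strict interdose
intervals, age ceilings on birth doses — and manual errors produce missed
opportunities for vaccination (MOVs): visits at which an eligible child
leaves without a due dose. Two persistent field errors are treating the
14-week inactivated polio (IPV) dose as if it depended on the third
pentavalent dose, and "locking" the 9-month measles dose behind Penta-3,
neither of which is part of the WHO-recommended schedule.

`vaxcast` is a decision-support engine plus the instruments needed to
evaluate one: an independent expert-rule oracle, diagnostic-accuracy
statistics, and a cohort simulator that reproduces those vaccinator error
behaviours, so a full accuracy study can be run end to end with synthetic
data. It is aimed at immunization-programme analysts and researchers who
study MOV reduction and electronic immunization registries.

## What's in the box

| Module | Role |
| --- | --- |
| `vaxcast.schedule` | EPI schedule model + built-in `pakistan_2019` / `bangladesh_2019` definitions and service calendars |
| `vaxcast.engine` | per-dose statuses (GIVEN / DUE_NOW / SCHEDULED / NOT_INDICATED), warnings, holiday-aware next-visit dates |
| `vaxcast.gold` | independent straight-line transcription of the expert due-dose rules (the evaluation reference) |
| `vaxcast.evaluation` | sensitivity/specificity/accuracy, binary-test ROC area (Se+Sp)/2, exact Clopper–Pearson CIs, MOV rates, study-table aggregation, packaged field-study counts |
| `vaxcast.simulate` | seeded synthetic cohorts with realistic visit delays and a parameterised vaccinator-error model |
| `vaxcast.cli` | `vaxcast forecast / evaluate / simulate` |

The forecasting rules in brief: each dose slot has a minimum age (exact
day counts for week-based ages; calendar addition with end-of-month
clamping for month/year-based ages), an optional strict interval from the
previous dose of the *same* series (">28 days" stored as 29), and an
optional age ceiling (birth OPV through day 28; BCG through the first
birthday). Prerequisites never cross series, so IPV and measles due-ness
are independent of pentavalent progress by construction. The plan is
recomputed at every visit, which yields catch-up schedules for free.

## Worked example

A child born 2019-07-01 makes first contact at six months, with an empty
card, at a center closed on Sundays and on New Year's Day:

```python
import datetime as dt
from vaxcast import ChildRecord, ServiceCalendar, builtin_schedule, forecast_visit

schedule = builtin_schedule("pakistan_2019")
child = ChildRecord(child_id="demo", dob=dt.date(2019, 7, 1))
cal = ServiceCalendar(service_weekdays=frozenset(range(6)),
                      public_holidays=frozenset({dt.date(2020, 1, 1)}))
forecast = forecast_visit(child, dt.date(2020, 1, 1), schedule, cal)
for s in forecast.statuses:
    print(f"{s.label:10s} {s.status.value:13s} {s.scheduled_date or ''}")
print("next visit:", forecast.next_visit_date)
```

prints

```
BCG        DUE_NOW
OPV-0      NOT_INDICATED
OPV-1      DUE_NOW
OPV-2      SCHEDULED     2020-01-30
OPV-3      SCHEDULED     2020-02-28
Penta-1    DUE_NOW
Penta-2    SCHEDULED     2020-01-30
Penta-3    SCHEDULED     2020-02-28
PCV-1      DUE_NOW
PCV-2      SCHEDULED     2020-01-30
PCV-3      SCHEDULED     2020-02-28
Rota-1     DUE_NOW
Rota-2     SCHEDULED     2020-01-30
IPV        DUE_NOW
Measles-1  SCHEDULED     2020-04-01
Measles-2  SCHEDULED     2020-10-01
next visit: 2020-01-30
```

Reading it: BCG is still indicated (under one year), the birth OPV dose
has aged out, the whole 6-week block — including IPV, due by age alone —
is given today, the second doses chain 29 days after today's projected
administrations, and measles waits for the 9-month birthday. The next
visit lands on 2020-01-30 because the 29-day interval, not the calendar,
binds; had it fallen on the holiday it would have rolled forward.

The same flow is available from the shell:

```bash
vaxcast forecast --schedule pakistan_2019 --records children.csv \
    --visit-date 2020-01-01 --out out/
vaxcast simulate --config sim.yaml --out out/
vaxcast evaluate --fixture-table2 --out out/
```

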