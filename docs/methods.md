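# Methods

## The forecasting model

`vaxcast` treats a national EPI schedule as a set of antigen series, each
an ordered list of dose rules. A rule has:

* **minimum age** — stored in days when the schedule quotes weeks
  (6 w = 42, 10 w = 70, 14 w = 98) and in calendar months/years when it
  quotes months or years. Calendar thresholds are resolved per child by
  calendar addition with clamping, so a child born 31 January reaches
  "+1 month" on 28/29 February and "9 months" on 31 October. The two
  conventions deliberately coexist: week-based ages are exact day counts
  everywhere, month-based ages follow the calendar the way a clinic reads
  a birthday.
* **minimum interval** — days since the previous dose of the same
  series. "More than 28 days after" is stored as 29 (strict inequality),
  so a 28-day gap never satisfies the rule and a 29-day gap always does.
* **maximum age** — an inclusive ceiling. The birth OPV dose is
  indicated through day 28 of life; BCG through the first birthday
  (calendar-year addition, clamped; the boundary day itself is eligible).
* **prerequisite** — only ever the previous dose of the same series.
  Cross-series dependencies are structurally impossible. This is the
  central correctness property: the 14-week IPV dose (one dose in
  Pakistan, second of two in Bangladesh) and the 9-month measles dose
  must never wait on pentavalent progress, because the belief that they
  do is precisely the documented source of field MOVs.

At a visit, every slot is classified: `GIVEN` (in history),
`NOT_INDICATED` (past its ceiling, or its prerequisite can no longer be
given), `DUE_NOW` (age floor met, prerequisite administered, interval
elapsed), else `SCHEDULED` with the earliest feasible date. For doses
whose prerequisite is not yet given, the earliest date chains off the
prerequisite's *projected* date (its own due/scheduled date) plus the
interval; because a dose due today projects to the visit date, its
successor is automatically at least one interval later — at most one dose
per series per visit without a special rule. Recomputing this plan at
every visit is what produces catch-up schedules for delayed children.

The next-visit proposal takes the earliest scheduled date and advances it
to the first day that is a service weekday, not a public holiday, and —
where per-antigen session days are configured — offers at least one of
the earliest-due antigens. When several antigens share the earliest date
but different session days, the earliest permissible day for *any* of
them is chosen (minimum delay; the remainder roll to their own days).
Dates never move backward.

Recording an administration warns (below minimum age, below interval,
past ceiling, missing prerequisite) but never blocks: off-schedule doses
happen in the field and the record must represent them. Duplicate doses
and dates before birth are hard errors.

### Third-dose age floor

The expert rule set for third doses of the 6-week block is applied at
≥14 weeks of age, consistent with the 6/10/14-week series; the quoted
"≥4 weeks" variant of that criterion is interpreted as a transcription
slip. Both the gold oracle and the schedule configs keep the floor as a
parameter (`third_dose_min_age_days`, default 98) so the literal reading
remains testable.

## The gold-standard oracle

`vaxcast.gold` re-implements the expert criteria as straight-line
per-dose predicates — no date search, no projection, no shared code with
the engine — exactly as a vaccines expert reads them off the schedule.
It judges due-ness only (no calendars). Oracle discipline is the point:
the engine's `DUE_NOW` set is required to equal `gold_due` on randomized
suites of 10,000 child/visit instances per country, where histories are
series prefixes with arbitrary, sometimes rule-violating dates and gaps
straddling the 28/29-day boundary.

## Diagnostic statistics

Each scheduler is scored per dose slot as a binary test over
(child, visit) decisions: Se = TP/(TP+FN), Sp = TN/(TN+FP), accuracy,
and the ROC area of a single-threshold test, (Se+Sp)/2. Confidence
intervals are exact Clopper–Pearson (beta-quantile form; validated in the
tests against direct binomial tail-sum inversion for all n ≤ 50), with
Wilson available via `ci_method="wilson"`. Empty margins (e.g. a slot
never due) yield flagged `None` components rather than errors. The MOV
rate is missed/due with the same exact interval. Percentages print at one
decimal, rounded half-up, matching the convention of the packaged study
table.

The packaged table (`vaxcast/data/table2_counts.csv`) carries the
per-antigen counts of a two-country field study (6,241 visits, 4,613
children). Aggregation recomputes site totals (13,039 and 4,922 due
doses), cross-site antigen rows and the grand total (17,961) by
summation; the study's own column headers carry slightly smaller n values
(13,036 / 4,920 / 17,956) that disagree with its printed rows — the
fixture follows the rows and the printed proportions. The Pakistan site's
single 14-week IPV dose appears under the label "IPV-2", as the study
table prints it; internally it is a one-dose series with no prerequisite.

## The cohort simulator

`simulate_cohort` emulates the registry data such a study collects:

* **Birth dates** uniform over a configurable window (default calendar
  year 2019).
* **Visit trajectory**: milestone visits at birth, 6, 10, 14 weeks, 9 and
  15 months, each delayed by a gamma-distributed offset (delays are
  non-negative and right-skewed, as field timeliness is). Default
  mean/SD per milestone are set so that simulated ages at vaccination
  match the study cohort's observed means and spreads — e.g. first
  pentavalent dose at 8.8 (SD 5.2) weeks against the 6-week target, i.e.
  a mean delay of 19.6 days (SD 36.4). Visit dates are forced strictly
  increasing.
* **Attendance**: each milestone visit is attended with probability 0.9
  (a default chosen as plausible for settings with fair coverage; the
  study reports no attendance process). Missed visits simply roll the
  pending doses forward.
* **Enrollment**: each child enters observation at an age drawn from the
  study's enrollment mix (72.6 / 15.1 / 11.4 / 0.9 percent in ≤6, 6–12,
  12–18, 18–24 months), uniform within the bin. Earlier visits become
  card history, administered exactly per the gold standard; a child whose
  milestones all precede enrollment contributes one catch-up visit.

At every observed visit the gold due set, the engine `DUE_NOW` set and
the simulated vaccinator's administered set are captured simultaneously;
the vaccinator's choices (not the gold set) feed the ongoing record, so
errors propagate to later visits as they would on a real card.

### The error model

The vaccinator starts from the gold due set and, independently per visit
with fixed probabilities, applies the documented error behaviours:

* `p_ipv_tied_to_penta3` — IPV withheld unless Penta-3 is given at this
  visit or already on record (the "IPV goes with Penta-3" belief);
* `p_measles_locked_on_penta3` — measles dose 1 withheld until Penta-3
  has been received;
* `p_calendar_month_interval` — a chained dose whose 29-day interval has
  elapsed but whose "+1 calendar month" has not is deferred;
* `p_weekend_unadjusted` — the appointment lands on a closed day and the
  family returns a day or two later (affects timing, not the set);
* `p_random_miss` — unstructured per-dose omission.

Doses are only ever removed, never added, so nothing past an age ceiling
can be administered. Probabilities are shared across vaccinators — the
underlying interview data gives the prevalence of beliefs, not
per-vaccinator rates — and card loss/recall error is not modelled.

`component_rates` counts, per mechanism, the visits at which it could
have fired (its *opportunities*) and the corresponding misses, so a
single active knob at probability p is recovered as misses/opportunities
≈ p; the tests require agreement within three binomial standard errors at
cohort size 2,000.

## Problem sizes and determinism

All randomness flows from one `numpy` generator per run, seeded
explicitly; identical configs and seeds reproduce simulator output byte
for byte. The shipped test suite uses cohorts of 150–800 children and
randomized oracle suites of 1,000 instances per country; the acceptance
script scales these to 2,000 children and 10,000 instances per country.
These sizes put Monte-Carlo standard errors well inside the tested
tolerances while keeping a full run in tens of seconds.

## Limitations

* The simulator reproduces marginal timeliness and error prevalences,
  not the joint attendance/delay process of any real site — passing
  recovery tests shows the machinery is correct, not that simulated MOV
  percentages forecast real ones (those depend on unobserved behaviour
  frequencies and are reproducible only from the packaged counts).
* Rotavirus age caps used in some WHO guidance are not part of the
  default rule set (the expert criteria state none); the schema supports
  adding `max_age_days` per dose where a programme applies one.
* Stock-outs, adverse events, maternal vaccines and UI concerns
  (colors, languages, reminders) are out of scope.
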