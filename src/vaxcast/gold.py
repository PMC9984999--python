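"""Gold-standard due-dose determination: the expert rule set, verbatim.

This module answers one question — which doses is this child due *today*
— by evaluating each WHO-recommended EPI criterion as a straight-line
predicate, exactly as a vaccines expert reads the rules off the schedule:

* BCG through the first birthday (inclusive);
* (Pakistan) birth OPV through day 28 of life (inclusive);
* first doses of the 6-week block at >= 6 weeks of age;
* second doses at >= 10 weeks of age and more than 28 days after the
  corresponding first dose;
* third doses at >= 14 weeks of age and more than 28 days after the
  second dose (the age floor is a parameter; see below);
* the 14-week IPV dose by age alone for Pakistan; for Bangladesh, IPV-1
  at >= 6 weeks and IPV-2 at >= 14 weeks and more than 28 days after
  IPV-1;
* measles (measles-rubella in Bangladesh) dose 1 at 9 months, dose 2 at
  15 months and more than 28 days after dose 1.

There is deliberately no shared logic with :mod:`vaxcast.engine` — no
date search, no projection, no schedule objects — so this can serve as an
independent oracle for the engine's DUE_NOW set. Due-ness only: holiday
adjustment and next-visit proposals are the engine's business.
"""

from __future__ import annotations

from dateutil.relativedelta import relativedelta

from vaxcast._dates import parse_date
from vaxcast.records import ChildRecord

Slot = tuple[str, int]

#: Default age floor (days) for third doses of the 6-week block. The rule
#: set is sometimes quoted with a lower catch-up floor; keeping it a
#: parameter lets both readings be evaluated.
THIRD_DOSE_MIN_AGE_DAYS = 98


def _due_chain_dose(
    child: ChildRecord,
    visit_date,
    antigen: str,
    idx: int,
    min_age_days: int,
) -> bool:
    """Dose ``idx`` >= ``min_age_days`` old and >28 d after dose ``idx-1``."""
    if child.has(antigen, idx):
        return False
    if (visit_date - child.dob).days < min_age_days:
        return False
    prev = child.date_of(antigen, idx - 1)
    return prev is not None and (visit_date - prev).days > 28


def gold_due(
    child: ChildRecord,
    visit_date,
    country_id: str,
    third_dose_min_age_days: int = THIRD_DOSE_MIN_AGE_DAYS,
) -> set[Slot]:
    """The set of ``(antigen, dose_index)`` due at ``visit_date``."""
    visit_date = parse_date(visit_date)
    if visit_date < child.dob:
        raise ValueError(f"visit date {visit_date} precedes birth {child.dob}")
    age_days = (visit_date - child.dob).days
    due: set[Slot] = set()

    def not_given(antigen: str, idx: int) -> bool:
        return not child.has(antigen, idx)

    # BCG at <= 1 year of age (calendar year, first birthday inclusive)
    if not_given("BCG", 1) and visit_date <= child.dob + relativedelta(years=1):
        due.add(("BCG", 1))

    if country_id == "pakistan_2019":
        # birth OPV dose at <= 28 days
        if not_given("OPV", 1) and age_days <= 28:
            due.add(("OPV", 1))
        # 6-week block (OPV dose_index 2 is the first post-birth OPV dose)
        for antigen, idx in [("Penta", 1), ("PCV", 1), ("Rota", 1), ("OPV", 2)]:
            if not_given(antigen, idx) and age_days >= 42:
                due.add((antigen, idx))
        # 10-week block: >= 10 weeks and >28 days after the first dose
        for antigen, idx in [("Penta", 2), ("PCV", 2), ("Rota", 2), ("OPV", 3)]:
            if _due_chain_dose(child, visit_date, antigen, idx, 70):
                due.add((antigen, idx))
        # 14-week block
        for antigen, idx in [("Penta", 3), ("PCV", 3), ("OPV", 4)]:
            if _due_chain_dose(child, visit_date, antigen, idx, third_dose_min_age_days):
                due.add((antigen, idx))
        # single IPV dose at >= 14 weeks, by age alone — no prerequisite
        if not_given("IPV", 1) and age_days >= 98:
            due.add(("IPV", 1))
        measles = "Measles"
    elif country_id == "bangladesh_2019":
        for antigen in ("Penta", "PCV", "OPV"):
            if not_given(antigen, 1) and age_days >= 42:
                due.add((antigen, 1))
            if _due_chain_dose(child, visit_date, antigen, 2, 70):
                due.add((antigen, 2))
            if _due_chain_dose(child, visit_date, antigen, 3, third_dose_min_age_days):
                due.add((antigen, 3))
        if not_given("IPV", 1) and age_days >= 42:
            due.add(("IPV", 1))
        if _due_chain_dose(child, visit_date, "IPV", 2, 98):
            due.add(("IPV", 2))
        measles = "MR"
    else:
        raise ValueError(f"no gold-standard rule set for country {country_id!r}")

    # measles / measles-rubella: 9 months; 15 months and >28 d after dose 1
    if not_given(measles, 1) and visit_date >= child.dob + relativedelta(months=9):
        due.add((measles, 1))
    if not_given(measles, 2) and visit_date >= child.dob + relativedelta(months=15):
        m1 = child.date_of(measles, 1)
        if m1 is not None and (visit_date - m1).days > 28:
            due.add((measles, 2))
    return due
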