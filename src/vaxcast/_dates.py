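"""Calendar arithmetic shared by the schedule model and forecasting engine.

Week-based age thresholds are exact day counts (6 weeks = 42 days).
Month- and year-based thresholds are resolved by calendar addition to the
date of birth, clamping to the last day of a short month (so a child born
on 31 January reaches "+1 month" on 28/29 February).
"""

from __future__ import annotations

import datetime as dt

from dateutil.relativedelta import relativedelta

ISO = "%Y-%m-%d"


def parse_date(value: str | dt.date) -> dt.date:
    """Coerce an ISO-8601 string (or date) to a :class:`datetime.date`."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.datetime.strptime(str(value).strip(), ISO).date()


def add_months(d: dt.date, months: int) -> dt.date:
    """``d`` plus calendar months, clamped to the end of short months."""
    return d + relativedelta(months=months)


def add_years(d: dt.date, years: int) -> dt.date:
    """``d`` plus calendar years (29 Feb clamps to 28 Feb)."""
    return d + relativedelta(years=years)


def age_on(dob: dt.date, on: dt.date) -> int:
    """Exact age in days on a given date.

    Raises ``ValueError`` if ``on`` precedes the date of birth.
    """
    dob, on = parse_date(dob), parse_date(on)
    if on < dob:
        raise ValueError(f"date {on} precedes date of birth {dob}")
    return (on - dob).days
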