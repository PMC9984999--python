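import datetime as dt

import numpy as np
import pytest

from vaxcast.records import AdministeredDose, ChildRecord
from vaxcast.schedule import ScheduleDefinition, builtin_schedule


@pytest.fixture(scope="session")
def pakistan() -> ScheduleDefinition:
    return builtin_schedule("pakistan_2019")


@pytest.fixture(scope="session")
def bangladesh() -> ScheduleDefinition:
    return builtin_schedule("bangladesh_2019")


def make_child(dob="2019-07-01", doses=(), child_id="c1") -> ChildRecord:
    """Shorthand: doses as (antigen, idx, iso-date) triples."""
    return ChildRecord(
        child_id=child_id,
        dob=dt.date.fromisoformat(dob) if isinstance(dob, str) else dob,
        history=tuple(
            AdministeredDose(a, i, dt.date.fromisoformat(d) if isinstance(d, str) else d)
            for a, i, d in doses
        ),
    )


def random_child_and_visit(
    rng: np.random.Generator, schedule: ScheduleDefinition
) -> tuple[ChildRecord, dt.date]:
    """A randomized (child, visit_date) instance for oracle concordance.

    Histories are series prefixes with arbitrary (sometimes rule-violating)
    dates and gaps, deliberately including the 28/29-day boundary, so the
    engine and the gold oracle are compared on catch-up and edge cases,
    not just on-schedule children.
    """
    dob = dt.date(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
    visit_age = int(rng.integers(0, 750))
    visit = dob + dt.timedelta(days=visit_age)
    gaps = [20, 25, 27, 28, 29, 30, 31, 35, 45, 60, 90]
    history = []
    for antigen, rules in schedule.series:
        k = int(rng.integers(0, len(rules) + 1))
        age = int(rng.integers(0, visit_age + 1)) if visit_age else 0
        for idx in range(1, k + 1):
            if idx > 1:
                age += int(rng.choice(gaps))
            if age > visit_age:
                break
            history.append(AdministeredDose(antigen, idx, dob + dt.timedelta(days=age)))
    child = ChildRecord(child_id="rnd", dob=dob, history=tuple(history))
    return child, visit
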