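"""Child immunization records: the engine's sole clinical input.

A :class:`ChildRecord` is a date of birth plus a dated administered-dose
history — exactly the information an electronic immunization registry
holds for a child. Records round-trip through a flat CSV (one row per
administered dose) and an equivalent nested JSON form; all dates ISO 8601.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from vaxcast._dates import parse_date

CSV_COLUMNS = ["child_id", "dob", "sex", "antigen", "dose_index", "date"]


class RecordError(ValueError):
    """A child record violates its invariants."""


@dataclass(frozen=True, order=True)
class AdministeredDose:
    antigen: str
    dose_index: int
    date: dt.date

    def __post_init__(self):
        object.__setattr__(self, "date", parse_date(self.date))


@dataclass(frozen=True)
class ChildRecord:
    """A child's identity, date of birth and administered-dose history.

    Invariants (checked by :meth:`validate`): every administration date is
    on/after the date of birth; within a series, dose *k* is not dated
    before dose *k−1*; no duplicate ``(antigen, dose_index)``.
    """

    child_id: str
    dob: dt.date
    sex: Optional[str] = None
    history: tuple[AdministeredDose, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "dob", parse_date(self.dob))
        object.__setattr__(self, "history", tuple(self.history))
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[str, int], dt.date] = {}
        for d in self.history:
            key = (d.antigen, d.dose_index)
            if key in seen:
                raise RecordError(
                    f"child {self.child_id}: duplicate dose {d.antigen}-{d.dose_index}"
                )
            if d.date < self.dob:
                raise RecordError(
                    f"child {self.child_id}: {d.antigen}-{d.dose_index} dated "
                    f"{d.date}, before birth {self.dob}"
                )
            seen[key] = d.date
        for (antigen, idx), date in seen.items():
            prev = seen.get((antigen, idx - 1))
            if prev is not None and date < prev:
                raise RecordError(
                    f"child {self.child_id}: {antigen}-{idx} dated {date} before "
                    f"{antigen}-{idx - 1} dated {prev}"
                )

    # -- history queries ------------------------------------------------
    def has(self, antigen: str, dose_index: int) -> bool:
        return any(
            d.antigen == antigen and d.dose_index == dose_index for d in self.history
        )

    def date_of(self, antigen: str, dose_index: int) -> Optional[dt.date]:
        for d in self.history:
            if d.antigen == antigen and d.dose_index == dose_index:
                return d.date
        return None

    def with_dose(self, antigen: str, dose_index: int, date) -> "ChildRecord":
        """A new record with one more administered dose (validated)."""
        dose = AdministeredDose(antigen, dose_index, parse_date(date))
        return replace(self, history=self.history + (dose,))

    def given_set(self) -> set[tuple[str, int]]:
        return {(d.antigen, d.dose_index) for d in self.history}


# -- CSV / JSON IO ------------------------------------------------------


def records_to_frame(children: Iterable[ChildRecord]) -> pd.DataFrame:
    rows = []
    for c in children:
        if not c.history:
            rows.append([c.child_id, c.dob.isoformat(), c.sex or "", "", "", ""])
        for d in sorted(c.history, key=lambda d: (d.date, d.antigen, d.dose_index)):
            rows.append(
                [
                    c.child_id,
                    c.dob.isoformat(),
                    c.sex or "",
                    d.antigen,
                    d.dose_index,
                    d.date.isoformat(),
                ]
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ChildRecord]:
    missing = [c for c in ("child_id", "dob") if c not in df.columns]
    if missing:
        raise RecordError(f"records table missing required column(s): {missing}")
    children: list[ChildRecord] = []
    for child_id, grp in df.groupby("child_id", sort=False):
        dobs = {parse_date(v) for v in grp["dob"]}
        if len(dobs) != 1:
            raise RecordError(f"child {child_id}: conflicting dates of birth {dobs}")
        sexes = set(grp["sex"].dropna().astype(str)) - {""} if "sex" in grp else set()
        history = []
        for _, row in grp.iterrows():
            antigen = str(row.get("antigen", "") or "").strip()
            if not antigen or pd.isna(row.get("dose_index")):
                continue
            history.append(
                AdministeredDose(antigen, int(row["dose_index"]), parse_date(row["date"]))
            )
        children.append(
            ChildRecord(
                child_id=str(child_id),
                dob=dobs.pop(),
                sex=sexes.pop() if sexes else None,
                history=tuple(history),
            )
        )
    return children


def read_records_csv(path) -> list[ChildRecord]:
    return frame_to_records(pd.read_csv(path, dtype={"child_id": str, "sex": str}))


def write_records_csv(children: Iterable[ChildRecord], path) -> None:
    records_to_frame(children).to_csv(path, index=False)


def records_to_json(children: Iterable[ChildRecord]) -> str:
    payload = [
        {
            "child_id": c.child_id,
            "dob": c.dob.isoformat(),
            "sex": c.sex,
            "doses": [
                {"antigen": d.antigen, "dose_index": d.dose_index, "date": d.date.isoformat()}
                for d in c.history
            ],
        }
        for c in children
    ]
    return json.dumps(payload, indent=2, sort_keys=True)


def records_from_json(text: str) -> list[ChildRecord]:
    return [
        ChildRecord(
            child_id=item["child_id"],
            dob=parse_date(item["dob"]),
            sex=item.get("sex"),
            history=tuple(
                AdministeredDose(d["antigen"], int(d["dose_index"]), parse_date(d["date"]))
                for d in item.get("doses", [])
            ),
        )
        for item in json.loads(text)
    ]
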