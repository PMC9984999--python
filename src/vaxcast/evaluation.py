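"""Diagnostic accuracy and missed-opportunity statistics.

A scheduler (decision-support engine or human vaccinator) is scored per
dose slot against the gold standard as a binary test over (child, visit)
decisions: TP = due and flagged/administered, FN = due but not, FP =
flagged though not due, TN = neither. From the 2x2 table we report
sensitivity, specificity, accuracy and the single-threshold ROC area
(Se + Sp) / 2, with exact (Clopper–Pearson) binomial confidence
intervals; Wilson intervals are available behind a flag.

The module also ships a packaged per-antigen count table from a
two-country field study of ~6.2k immunization visits, whose printed
proportions the aggregation reproduces. A missed opportunity for
vaccination (MOV) is a gold-standard-due dose not administered at that
visit; its rate is a simple binomial proportion.

Percentages are rounded half-up to one decimal, matching the reporting
style of the study tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

Slot = tuple[str, int]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 96.65 -> 96.7, never 96.6)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage to ``ndigits`` decimals, half-up."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


# -- exact and Wilson binomial intervals --------------------------------


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI via beta quantiles (equal-tailed)."""
    if not 0 <= k <= n or n == 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def wilson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval (the common non-exact alternative)."""
    if not 0 <= k <= n or n == 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    z = float(stats.norm.ppf(1 - alpha / 2))
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * ((p * (1 - p) / n + z * z / (4 * n * n)) ** 0.5) / denom
    # the score interval is degenerate at the boundaries; pin endpoints so
    # floating-point noise cannot place the limit on the wrong side of p
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return lo, hi


_CI_METHODS = {"clopper-pearson": clopper_pearson, "wilson": wilson}


# -- 2x2 machinery ------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-slot 2x2 of a scheduler's decisions against the gold standard."""

    antigen: str
    dose_index: int
    site: str
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagStats:
    """Point estimates and 95% CIs; a component is None if its margin is empty."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    auc: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity_ci: Optional[tuple[float, float]] = None
    accuracy_ci: Optional[tuple[float, float]] = None
    auc_ci: Optional[tuple[float, float]] = None
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity_ci": self.sensitivity_ci,
            "specificity_ci": self.specificity_ci,
            "accuracy_ci": self.accuracy_ci,
            "auc_ci": self.auc_ci,
            "undefined": list(self.undefined),
        }


def diag_stats(c: ConfusionCounts, ci_method: str = "clopper-pearson") -> DiagStats:
    """Sensitivity, specificity, accuracy and binary-test ROC area from a 2x2.

    For a single-threshold (binary) test the ROC curve is the broken line
    through (1-Sp, Se), so its area is (Se + Sp) / 2; the AUC interval is
    derived from the component intervals by the same average.
    """
    ci = _CI_METHODS[ci_method]
    undefined: list[str] = []
    se = sp = acc = auc = None
    se_ci = sp_ci = acc_ci = auc_ci = None
    if c.tp + c.fn > 0:
        se = c.tp / (c.tp + c.fn)
        se_ci = ci(c.tp, c.tp + c.fn)
    else:
        undefined.append("sensitivity")
    if c.fp + c.tn > 0:
        sp = c.tn / (c.fp + c.tn)
        sp_ci = ci(c.tn, c.fp + c.tn)
    else:
        undefined.append("specificity")
    if c.n > 0:
        acc = (c.tp + c.tn) / c.n
        acc_ci = ci(c.tp + c.tn, c.n)
    else:
        undefined.append("accuracy")
    if se is not None and sp is not None:
        auc = (se + sp) / 2
        auc_ci = ((se_ci[0] + sp_ci[0]) / 2, (se_ci[1] + sp_ci[1]) / 2)
    else:
        undefined.append("auc")
    return DiagStats(se, sp, acc, auc, se_ci, sp_ci, acc_ci, auc_ci, tuple(undefined))


def confusion_from_records(
    gold: Mapping[object, set[Slot]],
    predicted: Mapping[object, set[Slot]],
    site: str = "",
    slots: Optional[Sequence[Slot]] = None,
) -> list[ConfusionCounts]:
    """Per-slot 2x2 counts over a common (child, visit) universe.

    ``gold`` and ``predicted`` map the same visit keys to due / flagged
    slot sets. TN for a slot counts visits at which the slot was neither
    due nor flagged, so every visit contributes to every slot's table.
    """
    gkeys, pkeys = set(gold), set(predicted)
    if gkeys != pkeys:
        only_g = sorted(map(str, gkeys - pkeys))[:5]
        only_p = sorted(map(str, pkeys - gkeys))[:5]
        raise ValueError(
            f"visit universes differ: {len(gkeys - pkeys)} only in gold "
            f"(e.g. {only_g}), {len(pkeys - gkeys)} only in predicted (e.g. {only_p})"
        )
    if slots is None:
        seen: set[Slot] = set()
        for s in list(gold.values()) + list(predicted.values()):
            seen |= s
        slots = sorted(seen)
    n_visits = len(gkeys)
    out = []
    for slot in slots:
        tp = fn = fp = 0
        for key in gkeys:
            d, p = slot in gold[key], slot in predicted[key]
            tp += d and p
            fn += d and not p
            fp += p and not d
        out.append(
            ConfusionCounts(
                antigen=slot[0],
                dose_index=slot[1],
                site=site,
                tp=tp,
                fn=fn,
                fp=fp,
                tn=n_visits - tp - fn - fp,
            )
        )
    return out


# -- MOV rate -----------------------------------------------------------


@dataclass(frozen=True)
class MovRate:
    due: int
    missed: int
    proportion: float
    ci95: tuple[float, float]

    @property
    def percent(self) -> float:
        return pct(self.missed, self.due)


def mov_rate(due: int, missed: int, ci_method: str = "clopper-pearson") -> MovRate:
    """Missed-opportunity rate ``missed/due`` with an exact 95% CI."""
    if due <= 0:
        raise ValueError("mov_rate: 'due' must be positive")
    if not 0 <= missed <= due:
        raise ValueError("mov_rate: need 0 <= missed <= due")
    return MovRate(due, missed, missed / due, _CI_METHODS[ci_method](missed, due))


# -- study table --------------------------------------------------------


@dataclass(frozen=True)
class StudyRow:
    """One antigen-dose row: gold-due total and each arm's yes/no split."""

    site: str
    label: str
    due_gold: int
    idss_yes: int
    idss_no: int
    vacc_yes: int
    vacc_no: int

    def __post_init__(self):
        if min(self.due_gold, self.idss_yes, self.idss_no, self.vacc_yes, self.vacc_no) < 0:
            raise ValueError(f"row {self.site}/{self.label}: negative count")
        if self.idss_yes + self.idss_no != self.due_gold:
            raise ValueError(
                f"row {self.site}/{self.label}: idss_yes+idss_no != due_gold "
                f"({self.idss_yes}+{self.idss_no} != {self.due_gold})"
            )
        if self.vacc_yes + self.vacc_no != self.due_gold:
            raise ValueError(
                f"row {self.site}/{self.label}: vacc_yes+vacc_no != due_gold "
                f"({self.vacc_yes}+{self.vacc_no} != {self.due_gold})"
            )


@dataclass(frozen=True)
class StudyTable:
    """Validated per-site rows plus site, combined and grand totals."""

    rows: tuple[StudyRow, ...]
    site_totals: dict[str, StudyRow] = field(default_factory=dict)
    combined_rows: dict[str, StudyRow] = field(default_factory=dict)
    grand_total: Optional[StudyRow] = None

    def row(self, site: str, label: str) -> StudyRow:
        for r in self.rows:
            if r.site == site and r.label == label:
                return r
        raise KeyError((site, label))

    def percentages(self) -> pd.DataFrame:
        """Long-form frame with the printed-style one-decimal percentages."""
        records = []
        everything = list(self.rows)
        everything += list(self.site_totals.values())
        everything += list(self.combined_rows.values())
        if self.grand_total is not None:
            everything.append(self.grand_total)
        for r in everything:
            records.append(
                {
                    "site": r.site,
                    "label": r.label,
                    "due_gold": r.due_gold,
                    "idss_yes": r.idss_yes,
                    "idss_yes_pct": pct(r.idss_yes, r.due_gold),
                    "idss_no": r.idss_no,
                    "idss_no_pct": pct(r.idss_no, r.due_gold),
                    "vacc_yes": r.vacc_yes,
                    "vacc_yes_pct": pct(r.vacc_yes, r.due_gold),
                    "vacc_no": r.vacc_no,
                    "vacc_no_pct": pct(r.vacc_no, r.due_gold),
                }
            )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.percentages().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(self.percentages().to_dict(orient="records"), indent=2)


def _sum_rows(site: str, label: str, rows: Iterable[StudyRow]) -> StudyRow:
    rows = list(rows)
    return StudyRow(
        site=site,
        label=label,
        due_gold=sum(r.due_gold for r in rows),
        idss_yes=sum(r.idss_yes for r in rows),
        idss_no=sum(r.idss_no for r in rows),
        vacc_yes=sum(r.vacc_yes for r in rows),
        vacc_no=sum(r.vacc_no for r in rows),
    )


def aggregate_table(rows: Sequence[StudyRow]) -> StudyTable:
    """Site totals, cross-site per-antigen rows and the grand total by summation."""
    rows = tuple(rows)  # StudyRow validates itself on construction
    sites: dict[str, list[StudyRow]] = {}
    labels: dict[str, list[StudyRow]] = {}
    for r in rows:
        sites.setdefault(r.site, []).append(r)
        labels.setdefault(r.label, []).append(r)
    site_totals = {s: _sum_rows(s, "Total", rs) for s, rs in sites.items()}
    combined = {lb: _sum_rows("combined", lb, rs) for lb, rs in labels.items()}
    grand = _sum_rows("combined", "Total", rows) if rows else None
    return StudyTable(rows, site_totals, combined, grand)


def load_table2_fixture() -> StudyTable:
    """The packaged field-study per-antigen counts, aggregated."""
    with resources.files("vaxcast").joinpath("data/table2_counts.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    rows = [
        StudyRow(
            site=r.site,
            label=r.label,
            due_gold=int(r.due_gold),
            idss_yes=int(r.idss_yes),
            idss_no=int(r.idss_no),
            vacc_yes=int(r.vacc_yes),
            vacc_no=int(r.vacc_no),
        )
        for r in df.itertuples()
    ]
    return aggregate_table(rows)
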