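"""Screening-registry and cost-ledger tables: loading, validation, summaries.

The registry is a tidy table with one row per patient-year: whether the
patient attended screening that year, the diabetic-retinopathy (DR) grade
found, and the macular-oedema (DMO) status.  The cost ledger is a tidy table
of euro line items by calendar year and activity category.  The functions
here reproduce the aggregate arithmetic a screening programme reports
annually: incidence rates, per-patient costs, mean +/- sd summaries, and the
roll-up of DMO treatment cost components.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .util import round_half_up

__all__ = [
    "DR_GRADES",
    "DMO_STATUSES",
    "COST_CATEGORIES",
    "SchemaError",
    "ValidationError",
    "ScreeningRecord",
    "CostLineItem",
    "CostSummary",
    "CostSchedule",
    "load_registry",
    "load_cost_ledger",
    "write_registry",
    "write_cost_ledger",
    "annual_incidence",
    "per_patient_cost",
    "summarize_costs",
    "dmo_cost_rollup",
    "incidence_table",
]

logger = logging.getLogger(__name__)

#: Ordered DR severity grades (worst eye).
DR_GRADES = ("none", "mild", "moderate", "severe", "proliferative")
#: Macular-oedema status; ``csmo`` = clinically significant macular oedema.
DMO_STATUSES = ("none", "extrafoveal", "csmo")
#: Closed set of cost-ledger activity categories.
COST_CATEGORIES = ("screening", "diagnosis", "laser", "anti_vegf", "vitrectomy", "follow_up")

REGISTRY_COLUMNS = ("patient_id", "year", "age", "screened", "dr_grade", "dmo_status")
LEDGER_COLUMNS = ("year", "category", "amount")


class SchemaError(ValueError):
    """A table is missing required columns."""


class ValidationError(ValueError):
    """A row violates a record invariant."""


@dataclass(frozen=True)
class ScreeningRecord:
    """One patient-year observation from the screening registry."""

    patient_id: str
    year: int
    age: float
    screened: bool
    dr_grade: str
    dmo_status: str

    def __post_init__(self) -> None:
        if self.dr_grade not in DR_GRADES:
            raise ValidationError(
                f"unknown dr_grade {self.dr_grade!r}; expected one of {DR_GRADES}"
            )
        if self.dmo_status not in DMO_STATUSES:
            raise ValidationError(
                f"unknown dmo_status {self.dmo_status!r}; expected one of {DMO_STATUSES}"
            )
        if not self.age > 0:
            raise ValidationError(f"age must be > 0, got {self.age}")

    @property
    def stdr(self) -> bool:
        """Sight-threatening DR: severe or worse grade, or CSMO."""
        return self.dr_grade in ("severe", "proliferative") or self.dmo_status == "csmo"


@dataclass(frozen=True)
class CostLineItem:
    """One euro line item in the cost ledger."""

    year: int
    category: str
    amount: float

    def __post_init__(self) -> None:
        if self.category not in COST_CATEGORIES:
            raise ValidationError(
                f"unknown cost category {self.category!r}; expected one of {COST_CATEGORIES}"
            )
        if self.amount < 0:
            raise ValidationError(f"amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class CostSummary:
    """Mean +/- sd [min, max] summary of a set of euro amounts."""

    mean: float
    sd: float
    minimum: float
    maximum: float
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def rounded(self, ndigits: int = 2) -> "CostSummary":
        """Presentation-rounded copy (half-up)."""
        return CostSummary(
            mean=round_half_up(self.mean, ndigits),
            sd=round_half_up(self.sd, ndigits),
            minimum=round_half_up(self.minimum, ndigits),
            maximum=round_half_up(self.maximum, ndigits),
            n=self.n,
        )


class CostSchedule:
    """Unit costs (EUR) per screening/diagnosis/treatment activity.

    A thin validated mapping; see :func:`drscreen.synthetic.generate_cost_schedule`
    for the bundled default schedule.
    """

    def __init__(self, unit_costs: Mapping[str, float]):
        for key, value in unit_costs.items():
            if value < 0:
                raise ValidationError(f"unit cost {key!r} must be >= 0, got {value}")
        self._costs = dict(unit_costs)

    def __getitem__(self, key: str) -> float:
        return self._costs[key]

    def __contains__(self, key: str) -> bool:
        return key in self._costs

    def __eq__(self, other) -> bool:
        return isinstance(other, CostSchedule) and self._costs == other._costs

    def keys(self):
        return self._costs.keys()

    def as_dict(self) -> dict[str, float]:
        return dict(self._costs)

    def replace(self, **overrides: float) -> "CostSchedule":
        """Copy with some unit costs overridden; unknown keys raise ``KeyError``."""
        unknown = set(overrides) - set(self._costs)
        if unknown:
            raise KeyError(f"unknown cost schedule entries: {sorted(unknown)}")
        merged = {**self._costs, **overrides}
        return CostSchedule(merged)

    def __repr__(self) -> str:
        return f"CostSchedule({self._costs!r})"


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot interpret screened flag {value!r} as boolean")


def load_registry(path: str | Path) -> list[ScreeningRecord]:
    """Load and validate a screening-registry CSV.

    The file must carry the columns ``patient_id, year, age, screened,
    dr_grade, dmo_status``.  Every row is validated against the record
    invariants; a patient may appear at most once per calendar year.
    """
    df = pd.read_csv(path)
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"registry file {path} is missing columns {sorted(missing)}")
    records: list[ScreeningRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                ScreeningRecord(
                    patient_id=str(row.patient_id),
                    year=int(row.year),
                    age=float(row.age),
                    screened=_parse_bool(row.screened),
                    dr_grade=str(row.dr_grade),
                    dmo_status=str(row.dmo_status),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"registry row {i}: {exc}") from exc
    seen: set[tuple[str, int]] = set()
    for i, rec in enumerate(records):
        key = (rec.patient_id, rec.year)
        if key in seen:
            raise ValidationError(
                f"registry row {i}: duplicate record for patient {rec.patient_id!r} in {rec.year}"
            )
        seen.add(key)
    logger.info("loaded %d screening records from %s", len(records), path)
    return records


def load_cost_ledger(path: str | Path) -> list[CostLineItem]:
    """Load and validate a cost-ledger CSV (columns ``year, category, amount``)."""
    df = pd.read_csv(path)
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"ledger file {path} is missing columns {sorted(missing)}")
    items: list[CostLineItem] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            items.append(
                CostLineItem(year=int(row.year), category=str(row.category), amount=float(row.amount))
            )
        except ValidationError as exc:
            raise ValidationError(f"ledger row {i}: {exc}") from exc
    logger.info("loaded %d cost line items from %s", len(items), path)
    return items


def registry_frame(records: Iterable[ScreeningRecord]) -> pd.DataFrame:
    """Registry records as a tidy DataFrame."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(REGISTRY_COLUMNS))


def ledger_frame(items: Iterable[CostLineItem]) -> pd.DataFrame:
    """Cost line items as a tidy DataFrame."""
    return pd.DataFrame([dataclasses.asdict(x) for x in items], columns=list(LEDGER_COLUMNS))


def write_registry(records: Iterable[ScreeningRecord], path: str | Path) -> None:
    registry_frame(records).to_csv(path, index=False)


def write_cost_ledger(items: Iterable[CostLineItem], path: str | Path) -> None:
    ledger_frame(items).to_csv(path, index=False)


def annual_incidence(cases: int, screened: int) -> float:
    """Annual incidence among screened patients, as a percentage (2 decimals).

    ``100 * cases / screened`` rounded half-up.
    """
    if screened <= 0:
        raise ValueError(f"screened count must be > 0, got {screened}")
    if not 0 <= cases <= screened:
        raise ValueError(f"cases must lie in [0, screened]; got {cases} of {screened}")
    return round_half_up(100.0 * cases / screened, 2)


def per_patient_cost(total: float, n: int) -> float:
    """Mean euro cost per patient (2 decimals, half-up)."""
    if n <= 0:
        raise ValueError(f"patient count must be > 0, got {n}")
    return round_half_up(total / n, 2)


def summarize_costs(values: Sequence[float]) -> CostSummary:
    """Mean, sample sd (n-1), min, max of a non-empty set of euro amounts.

    Values are returned unrounded; use :meth:`CostSummary.rounded` for
    presentation.  A single value has sd 0 by convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list of costs")
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return CostSummary(
        mean=float(arr.mean()),
        sd=sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n=int(arr.size),
    )


def dmo_cost_rollup(components: Sequence[CostLineItem]) -> tuple[float, float]:
    """Roll up one year's DMO cost components.

    Returns ``(treatment_total, grand_total)`` where the treatment total sums
    every non-diagnosis line (laser, anti-VEGF, vitrectomy, follow-up) and
    the grand total adds the single diagnosis line, if present.
    """
    diagnosis_lines = [c for c in components if c.category == "diagnosis"]
    if len(diagnosis_lines) > 1:
        raise ValidationError(
            f"expected at most one diagnosis line per year, got {len(diagnosis_lines)}"
        )
    for c in components:
        if c.amount < 0:  # CostLineItem already enforces this; guard raw inputs
            raise ValidationError(f"negative amount {c.amount} in {c.category}")
    treatment_total = float(sum(c.amount for c in components if c.category != "diagnosis"))
    diagnosis = float(sum(c.amount for c in diagnosis_lines))
    return treatment_total, treatment_total + diagnosis


def incidence_table(records: Iterable[ScreeningRecord]) -> pd.DataFrame:
    """Per-year screening and incidence summary of a registry.

    One row per calendar year with screened counts, new any-DR / per-grade /
    sight-threatening-DR / DMO counts among screened patients, and the
    corresponding incidence percentages.
    """
    df = registry_frame(records)
    rows = []
    for year, g in df.groupby("year", sort=True):
        scr = g[g["screened"]]
        n = len(scr)
        any_dr = int((scr["dr_grade"] != "none").sum())
        by_grade = {f"{grade}_dr": int((scr["dr_grade"] == grade).sum()) for grade in DR_GRADES[1:]}
        stdr = int(
            (
                scr["dr_grade"].isin(["severe", "proliferative"]) | (scr["dmo_status"] == "csmo")
            ).sum()
        )
        dmo = int((scr["dmo_status"] != "none").sum())
        row = {
            "year": int(year),
            "screened": n,
            "any_dr": any_dr,
            **by_grade,
            "stdr": stdr,
            "dmo": dmo,
        }
        for name in ("any_dr", "stdr", "dmo"):
            row[f"{name}_incidence_pct"] = annual_incidence(row[name], n) if n else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
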