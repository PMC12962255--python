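"""Household cohort data model and CSV I/O.

A cohort is an ordered collection of households, each described by the
handful of financial facts the downstream models need: age and gender
(for the disability hazard lookup), gross annual income (for the tax
engine), savings split into a liquid tier and a retirement tier (the
distinction that separates the stress-test scenarios), and the monthly
housing cost, which is the only recurring expense modeled. An optional
survey weight supports weighted aggregation; it defaults to 1.

The canonical on-disk form is a plain CSV with header::

    id,age,gender,gross_income,liquid_savings,retirement_savings,monthly_housing,weight

Foreign files (e.g. extracts from household finance surveys) can be
loaded through a ``column_map`` that aliases their column names onto
this schema.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "Gender",
    "HouseholdRecord",
    "Cohort",
    "COHORT_COLUMNS",
    "load_cohort",
    "save_cohort",
    "restrict_age",
    "age_band",
]


class Gender(str, enum.Enum):
    """Gender as used by actuarial disability tables (two categories)."""

    MALE = "male"
    FEMALE = "female"


#: Canonical CSV column order.
COHORT_COLUMNS = (
    "id",
    "age",
    "gender",
    "gross_income",
    "liquid_savings",
    "retirement_savings",
    "monthly_housing",
    "weight",
)

_MONEY_FIELDS = (
    "gross_income",
    "liquid_savings",
    "retirement_savings",
    "monthly_housing",
)


@dataclass(frozen=True)
class HouseholdRecord:
    """One household: demographics, income, savings split, housing cost.

    Monetary fields are annual USD except ``monthly_housing`` (USD per
    month) and the savings stocks (USD). ``after_tax_income`` is derived
    by the tax engine and is ``None`` until it has been applied.
    """

    id: str
    age: int
    gender: Gender
    gross_income: float
    liquid_savings: float
    retirement_savings: float
    monthly_housing: float
    weight: float = 1.0
    after_tax_income: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gender", Gender(self.gender))
        for name in _MONEY_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"household {self.id!r}: {name} must be finite and >= 0, got {v!r}"
                )
        if not math.isfinite(self.weight) or self.weight < 0:
            raise ValidationError(
                f"household {self.id!r}: weight must be finite and >= 0"
            )
        if self.after_tax_income is not None:
            if not math.isfinite(self.after_tax_income) or self.after_tax_income < 0:
                raise ValidationError(
                    f"household {self.id!r}: after_tax_income must be finite and >= 0"
                )

    @property
    def total_savings(self) -> float:
        return self.liquid_savings + self.retirement_savings


@dataclass(frozen=True)
class Cohort:
    """An ordered, id-unique collection of households."""

    records: tuple[HouseholdRecord, ...]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValidationError(f"duplicate household id {r.id!r} in cohort")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HouseholdRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame in canonical column order."""
        rows = [
            {
                "id": r.id,
                "age": r.age,
                "gender": r.gender.value,
                "gross_income": r.gross_income,
                "liquid_savings": r.liquid_savings,
                "retirement_savings": r.retirement_savings,
                "monthly_housing": r.monthly_housing,
                "weight": r.weight,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def load_cohort(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    savings_split: float = 0.5,
) -> Cohort:
    """Read a cohort CSV, optionally aliasing foreign column names.

    ``column_map`` maps schema field names to the file's column names,
    e.g. ``{"gross_income": "ppincome"}``; unmapped fields use their
    canonical names. Files from surveys that report a single combined
    savings figure may map it to the pseudo-field ``total_savings``,
    which is split ``savings_split`` liquid / ``1 - savings_split``
    retirement (the split is not observable in such surveys).

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for bad values (with the 0-based row index).
    """

    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    cmap = dict(column_map or {})
    if not 0.0 <= savings_split <= 1.0:
        raise ValidationError(f"savings_split must be in [0, 1], got {savings_split}")

    split_total = "total_savings" in cmap
    wanted = [c for c in COHORT_COLUMNS if c != "weight"]
    if split_total:
        wanted = [c for c in wanted if c not in ("liquid_savings", "retirement_savings")]
        wanted.append("total_savings")

    resolved: dict[str, str] = {}
    for field_name in wanted:
        col = cmap.get(field_name, field_name)
        if col not in df.columns:
            raise SchemaError(
                f"{path}: required column {col!r} (schema field {field_name!r}) not found"
            )
        resolved[field_name] = col
    weight_col = cmap.get("weight", "weight")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))

        def get(field_name: str) -> object:
            return rowd[resolved[field_name]]

        def money(field_name: str) -> float:
            raw = get(field_name)
            try:
                v = float(raw)
            except (TypeError, ValueError):
                v = float("nan")
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{path} row {i}: column {resolved[field_name]!r} must be a "
                    f"nonnegative number, got {raw!r}"
                )
            return v

        if split_total:
            total = money("total_savings")
            liquid = savings_split * total
            retirement = total - liquid
        else:
            liquid = money("liquid_savings")
            retirement = money("retirement_savings")

        weight = 1.0
        if weight_col in df.columns:
            raw_w = rowd[weight_col]
            if raw_w is not None and not (isinstance(raw_w, float) and math.isnan(raw_w)):
                weight = float(raw_w)

        try:
            rec = HouseholdRecord(
                id=str(get("id")),
                age=int(get("age")),
                gender=Gender(str(get("gender")).strip().lower()),
                gross_income=money("gross_income"),
                liquid_savings=liquid,
                retirement_savings=retirement,
                monthly_housing=money("monthly_housing"),
                weight=weight,
            )
        except ValueError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        records.append(rec)

    return Cohort(records=tuple(records), provenance=str(path))


def save_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as canonical CSV; returns the path written."""
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path


def restrict_age(cohort: Cohort, min_age: int = 35, max_age: int = 64) -> Cohort:
    """Keep households with ``min_age <= age <= max_age`` (both inclusive).

    The default window targets the ages at meaningful risk of the
    modeled disease while typically still in the workforce.
    """
    if min_age > max_age:
        raise ValueError(f"min_age ({min_age}) must be <= max_age ({max_age})")
    kept = tuple(r for r in cohort.records if min_age <= r.age <= max_age)
    return Cohort(records=kept, provenance=cohort.provenance)


def age_band(age: int) -> str:
    """10-year reporting band for an age in 35..64 (e.g. ``'45-54'``)."""
    if not 35 <= age <= 64:
        raise ValueError(f"age {age} outside 35..64")
    lo = 35 + 10 * ((age - 35) // 10)
    return f"{lo}-{lo + 9}"


def with_after_tax(record: HouseholdRecord, after_tax_income: float) -> HouseholdRecord:
    """Copy of ``record`` with ``after_tax_income`` set."""
    return replace(record, after_tax_income=after_tax_income)
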