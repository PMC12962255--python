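"""Actuarially fair catastrophic income-loss insurance premiums.

The pricing model is a two-state, one-year lottery. A household of age
``a`` either stays well — keeping one year of after-tax income ``Wg`` —
or becomes fully disabled before the terminal age, in which case its
wealth is ``Wb = 0`` (no benefits) or the average annual SSDI benefit
``Wb_SSDI``. The disability probability ``Prb`` is cumulated from a
table of annual hazards by age and gender:

    Prb(a) = 1 - prod_{t=a}^{T-1} (1 - h(t, gender)),   T = terminal age (65)

The actuarially fair premium equals the expected loss:

    premium = income - E[wealth]
            = Prb * Wg                      (no benefits)
            = Prb * (Wg - Wb_SSDI)          (with SSDI offset)

Per-household premiums are summed (optionally survey-weighted) and
scaled to the national population by ``round(population / respondents)``.
All arithmetic runs at full float precision; dollars are rounded only
for reporting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort import Cohort, Gender, HouseholdRecord
from .errors import LookupError_, ValidationError

__all__ = [
    "DEFAULT_SSDI_BENEFIT",
    "DEFAULT_POPULATION_35_64",
    "DisabilityTable",
    "PremiumResult",
    "AggregatePremium",
    "load_hazard_table",
    "save_hazard_table",
    "cumulative_disability_prob",
    "expected_wealth",
    "fair_premium",
    "price_household",
    "price_cohort",
    "aggregate_premiums",
    "premium_frame",
]

#: Average annual SSDI benefit, USD (2023).
DEFAULT_SSDI_BENEFIT = 17_868.0
#: US residents aged 35-64 in 2023 (Census Bureau estimate).
DEFAULT_POPULATION_35_64 = 126_651_558


@dataclass(frozen=True)
class DisabilityTable:
    """Annual disability hazards by (age, gender) up to a terminal age."""

    entries: Mapping[tuple[int, Gender], float]
    terminal_age: int = 65

    def __post_init__(self) -> None:
        norm = {}
        for (age, gender), h in self.entries.items():
            if not 0.0 <= h <= 1.0:
                raise ValidationError(
                    f"hazard for age {age}, {gender}: {h} outside [0, 1]"
                )
            norm[(int(age), Gender(gender))] = float(h)
        object.__setattr__(self, "entries", norm)

    @property
    def ages(self) -> tuple[int, ...]:
        return tuple(sorted({a for a, _ in self.entries}))

    def hazard(self, age: int, gender: Gender) -> float:
        key = (int(age), Gender(gender))
        if key not in self.entries:
            raise LookupError_(
                f"no hazard entry for age {key[0]}, gender {key[1].value}"
            )
        return self.entries[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age": a, "gender": g.value, "annual_hazard": h}
            for (a, g), h in sorted(self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
        ]
        return pd.DataFrame(rows, columns=["age", "gender", "annual_hazard"])


def load_hazard_table(path: str | Path, terminal_age: int = 65) -> DisabilityTable:
    """Read a hazard table CSV with header ``age,gender,annual_hazard``."""
    df = pd.read_csv(path)
    missing = {"age", "gender", "annual_hazard"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: hazard table missing columns {sorted(missing)}")
    entries = {
        (int(r.age), Gender(str(r.gender).strip().lower())): float(r.annual_hazard)
        for r in df.itertuples(index=False)
    }
    return DisabilityTable(entries=entries, terminal_age=terminal_age)


def save_hazard_table(table: DisabilityTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def cumulative_disability_prob(age: int, gender: Gender, table: DisabilityTable) -> float:
    """Probability of becoming disabled between ``age`` and the terminal age.

    Complement of surviving every annual hazard from ``age`` through
    ``terminal_age - 1``.
    """
    surv = 1.0
    for a in range(int(age), table.terminal_age):
        surv *= 1.0 - table.hazard(a, gender)
    return 1.0 - surv


def expected_wealth(Wg: float, Prb: float, disabled_wealth: float = 0.0) -> float:
    """Probability-weighted wealth across the well and disabled states."""
    if not 0.0 <= Prb <= 1.0:
        raise ValueError(f"Prb must be in [0, 1], got {Prb}")
    if Wg < 0 or disabled_wealth < 0:
        raise ValueError("wealth values must be >= 0")
    return Wg * (1.0 - Prb) + disabled_wealth * Prb


def fair_premium(after_tax_income: float, expected: float) -> float:
    """Actuarially fair premium: income minus expected wealth."""
    if after_tax_income < 0 or expected < 0:
        raise ValueError("inputs must be >= 0")
    return after_tax_income - expected


@dataclass(frozen=True)
class PremiumResult:
    """Full pricing breakdown for one household."""

    household_id: str
    age: int
    gender: Gender
    Wg: float
    Prg: float
    Wb: float
    Wb_SSDI: float
    Prb: float
    expected_wealth_no_ssdi: float
    expected_wealth_ssdi: float
    premium_no_ssdi: float
    premium_ssdi: float
    weight: float = 1.0


def price_household(
    record: HouseholdRecord,
    table: Optional[DisabilityTable] = None,
    ssdi_benefit: float = DEFAULT_SSDI_BENEFIT,
    prb_override: Optional[float] = None,
) -> PremiumResult:
    """Price the fair premium for one household, with and without SSDI.

    ``Prb`` comes from the cumulative hazard product unless
    ``prb_override`` supplies it directly (useful when a published
    probability is to be reproduced exactly).
    """
    if record.after_tax_income is None:
        raise ValidationError(
            f"household {record.id!r}: after_tax_income not set; run apply_taxes first"
        )
    if prb_override is not None:
        if not 0.0 <= prb_override <= 1.0:
            raise ValidationError(f"prb_override {prb_override} outside [0, 1]")
        prb = float(prb_override)
    else:
        if table is None:
            raise ValidationError("either a DisabilityTable or prb_override is required")
        prb = cumulative_disability_prob(record.age, record.gender, table)

    Wg = record.after_tax_income
    ew_no = expected_wealth(Wg, prb, 0.0)
    ew_ssdi = expected_wealth(Wg, prb, ssdi_benefit)
    return PremiumResult(
        household_id=record.id,
        age=record.age,
        gender=record.gender,
        Wg=Wg,
        Prg=1.0 - prb,
        Wb=0.0,
        Wb_SSDI=ssdi_benefit,
        Prb=prb,
        expected_wealth_no_ssdi=ew_no,
        expected_wealth_ssdi=ew_ssdi,
        premium_no_ssdi=fair_premium(Wg, ew_no),
        premium_ssdi=fair_premium(Wg, ew_ssdi),
        weight=record.weight,
    )


def price_cohort(
    cohort: Cohort,
    table: DisabilityTable,
    ssdi_benefit: float = DEFAULT_SSDI_BENEFIT,
) -> list[PremiumResult]:
    """Price every household in a cohort against a hazard table."""
    return [price_household(r, table, ssdi_benefit) for r in cohort]


@dataclass(frozen=True)
class AggregatePremium:
    """Cohort premium sums scaled to a national population."""

    cohort_sum_no_ssdi: float
    cohort_sum_ssdi: float
    population_size: int
    respondent_count: int
    scale_multiple: int
    scaled_total_no_ssdi: float
    scaled_total_ssdi: float

    def to_dict(self) -> dict:
        return asdict(self)


def aggregate_premiums(
    results: Sequence[PremiumResult],
    population_size: int = DEFAULT_POPULATION_35_64,
    weighted: bool = True,
    loading_factor: float = 1.0,
) -> AggregatePremium:
    """Sum per-household premiums and scale to the population.

    The scale multiple is the population size divided by the respondent
    count, rounded to the nearest integer. ``loading_factor`` multiplies
    both totals (1 = actuarially fair, no load).
    """
    if not results:
        raise ValueError("cannot aggregate an empty collection of premium results")
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    w = (lambda r: r.weight) if weighted else (lambda r: 1.0)
    sum_no = loading_factor * sum(r.premium_no_ssdi * w(r) for r in results)
    sum_ssdi = loading_factor * sum(r.premium_ssdi * w(r) for r in results)
    multiple = round(population_size / len(results))
    return AggregatePremium(
        cohort_sum_no_ssdi=sum_no,
        cohort_sum_ssdi=sum_ssdi,
        population_size=int(population_size),
        respondent_count=len(results),
        scale_multiple=multiple,
        scaled_total_no_ssdi=sum_no * multiple,
        scaled_total_ssdi=sum_ssdi * multiple,
    )


def premium_frame(results: Sequence[PremiumResult]) -> pd.DataFrame:
    """Premium results as a DataFrame for CSV export."""
    return pd.DataFrame(
        [
            {
                "id": r.household_id,
                "age": r.age,
                "gender": r.gender.value,
                "Wg": r.Wg,
                "Prb": r.Prb,
                "premium_no_ssdi": r.premium_no_ssdi,
                "premium_ssdi": r.premium_ssdi,
            }
            for r in results
        ]
    )
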