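"""Monthly cash-flow simulation under income-loss scenarios.

Each household enters a scenario with an opening cash balance equal to
the savings tier the scenario lets it access, then each month receives
``income_fraction`` of one month of after-tax income and pays its
housing cost. Housing is the only modeled expense and stays constant;
the income loss persists for the whole horizon. A household is
*insolvent* the first month its balance drops strictly below zero after
paying housing (a balance of exactly zero means the month's expenses
were just covered); once insolvent, always insolvent. Cohort-level
results are weighted cumulative insolvency curves by month.

The standard suite of three scenarios mirrors a cancer-treatment income
shock: total income loss with only liquid savings to draw on, a 50%
income reduction (some income support), and total income loss but with
retirement savings liquidatable. An optional haircut fraction can model
early-withdrawal penalties on liquidated retirement funds (default 0).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import Cohort, HouseholdRecord
from .errors import ValidationError

__all__ = [
    "SavingsAccess",
    "StressScenario",
    "SolvencyTrajectory",
    "InsolvencyCurve",
    "STANDARD_SCENARIOS",
    "accessible_savings",
    "simulate_household",
    "insolvency_curve",
    "run_stress_suite",
]


class SavingsAccess(str, enum.Enum):
    NONE = "none"
    LIQUID = "liquid"
    LIQUID_PLUS_RETIREMENT = "liquid_plus_retirement"


@dataclass(frozen=True)
class StressScenario:
    """An income-shock specification.

    ``income_fraction`` is the share of after-tax income retained
    throughout the horizon; ``savings_access`` selects which savings
    tiers form the opening buffer; ``retirement_haircut`` is the
    fraction of retirement savings lost to penalties on liquidation.
    """

    name: str
    income_fraction: float
    savings_access: SavingsAccess
    horizon_months: int = 6
    retirement_haircut: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "savings_access", SavingsAccess(self.savings_access))
        if not 0.0 <= self.income_fraction <= 1.0:
            raise ValidationError("income_fraction must be in [0, 1]")
        if self.horizon_months < 1:
            raise ValidationError("horizon_months must be >= 1")
        if not 0.0 <= self.retirement_haircut <= 1.0:
            raise ValidationError("retirement_haircut must be in [0, 1]")


@dataclass(frozen=True)
class SolvencyTrajectory:
    """Per-household monthly balance path and first insolvent month."""

    household_id: str
    opening_balance: float
    monthly_balance: tuple[float, ...]
    first_insolvent_month: Optional[int]  # 1-based; None if solvent throughout


@dataclass(frozen=True)
class InsolvencyCurve:
    """Weighted cumulative insolvency fraction by month (1-based)."""

    scenario: str
    rate_by_month: tuple[float, ...]

    def rate_at(self, month: int) -> float:
        return self.rate_by_month[month - 1]


def standard_scenarios(
    horizon_months: int = 6, retirement_haircut: float = 0.0
) -> tuple[StressScenario, StressScenario, StressScenario]:
    """The three standard stress tests over a common horizon.

    Test 1: no income, liquid savings buffer. Test 2: half income,
    liquid savings. Test 3: no income, liquid plus retirement savings.
    """
    return (
        StressScenario("test1_no_income", 0.0, SavingsAccess.LIQUID, horizon_months),
        StressScenario("test2_half_income", 0.5, SavingsAccess.LIQUID, horizon_months),
        StressScenario(
            "test3_liquidate_retirement",
            0.0,
            SavingsAccess.LIQUID_PLUS_RETIREMENT,
            horizon_months,
            retirement_haircut,
        ),
    )


STANDARD_SCENARIOS = standard_scenarios()


def accessible_savings(record: HouseholdRecord, scenario: StressScenario) -> float:
    """Opening cash buffer a scenario grants a household."""
    access = scenario.savings_access
    if access is SavingsAccess.NONE:
        return 0.0
    if access is SavingsAccess.LIQUID:
        return record.liquid_savings
    return record.liquid_savings + (1.0 - scenario.retirement_haircut) * record.retirement_savings


def simulate_household(
    record: HouseholdRecord, scenario: StressScenario
) -> SolvencyTrajectory:
    """Run the monthly cash-flow recursion for one household.

    Month ``m`` balance is ``opening + m * (income_fraction *
    after_tax_income / 12 - monthly_housing)``; the first month with a
    strictly negative balance (if any) is the first insolvent month.
    """
    if record.after_tax_income is None:
        raise ValidationError(
            f"household {record.id!r}: after_tax_income not set; run apply_taxes first"
        )
    opening = accessible_savings(record, scenario)
    monthly_net = scenario.income_fraction * record.after_tax_income / 12.0
    delta = monthly_net - record.monthly_housing

    balances = []
    first_insolvent: Optional[int] = None
    for m in range(1, scenario.horizon_months + 1):
        bal = opening + m * delta  # closed form avoids accumulated rounding
        balances.append(bal)
        if first_insolvent is None and bal < 0.0:
            first_insolvent = m
    return SolvencyTrajectory(
        household_id=record.id,
        opening_balance=opening,
        monthly_balance=tuple(balances),
        first_insolvent_month=first_insolvent,
    )


def insolvency_curve(cohort: Cohort, scenario: StressScenario) -> InsolvencyCurve:
    """Weighted fraction of households insolvent by each month.

    Insolvency is absorbing, so the curve is non-decreasing. Raises for
    an empty cohort (the rate is undefined).
    """
    if len(cohort) == 0:
        raise ValueError("insolvency rate undefined for an empty cohort")
    total_weight = sum(r.weight for r in cohort)
    if total_weight <= 0:
        raise ValueError("cohort has zero total weight")

    insolvent_weight = [0.0] * scenario.horizon_months
    for rec in cohort:
        traj = simulate_household(rec, scenario)
        if traj.first_insolvent_month is not None:
            for m in range(traj.first_insolvent_month - 1, scenario.horizon_months):
                insolvent_weight[m] += rec.weight
    rates = tuple(w / total_weight for w in insolvent_weight)
    return InsolvencyCurve(scenario=scenario.name, rate_by_month=rates)


def run_stress_suite(
    cohort: Cohort, horizon_months: int = 6, retirement_haircut: float = 0.0
) -> tuple[InsolvencyCurve, InsolvencyCurve, InsolvencyCurve]:
    """Insolvency curves for the three standard stress tests."""
    return tuple(
        insolvency_curve(cohort, sc)
        for sc in standard_scenarios(horizon_months, retirement_haircut)
    )
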