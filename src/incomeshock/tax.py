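"""Progressive federal tax brackets plus a flat effective state rate.

Gross annual income is converted to after-tax income as

    net = gross - federal_tax(gross - deduction) - state_rate * gross

where ``federal_tax`` applies each bracket's marginal rate to the slice
of income falling inside that bracket. The packaged default schedule is
the 2023 US federal schedule (single filer) with a 3.8% flat effective
state rate standing in for the wide variation across states. Brackets
apply to gross income directly: no standard deduction or credits are
assumed (``deduction`` defaults to 0 and is offered for sensitivity
analysis only), and the state rate is a share of gross, not of federal
taxable income.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .cohort import Cohort, HouseholdRecord, with_after_tax
from .errors import ValidationError

__all__ = [
    "TaxSchedule",
    "load_tax_schedule",
    "default_schedule",
    "federal_tax",
    "after_tax_income",
    "apply_taxes",
]


@dataclass(frozen=True)
class TaxSchedule:
    """Ordered marginal brackets, a flat state rate, optional deduction.

    ``brackets`` is a sequence of ``(lower_bound, marginal_rate)``
    pairs; the first lower bound must be 0 and bounds must increase
    strictly. Rates lie in [0, 1).
    """

    brackets: tuple[tuple[float, float], ...]
    state_effective_rate: float = 0.038
    filing_status: str = "single"
    deduction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "brackets", tuple((float(lo), float(r)) for lo, r in self.brackets)
        )
        if not self.brackets:
            raise ValidationError("tax schedule needs at least one bracket")
        if self.brackets[0][0] != 0.0:
            raise ValidationError("first bracket must start at 0")
        lowers = [lo for lo, _ in self.brackets]
        if any(b <= a for a, b in zip(lowers, lowers[1:])):
            raise ValidationError("bracket lower bounds must increase strictly")
        for lo, r in self.brackets:
            if not 0.0 <= r < 1.0:
                raise ValidationError(f"marginal rate {r} outside [0, 1)")
        if not 0.0 <= self.state_effective_rate < 1.0:
            raise ValidationError("state_effective_rate must be in [0, 1)")
        if self.deduction < 0:
            raise ValidationError("deduction must be >= 0")

    @property
    def top_rate(self) -> float:
        return self.brackets[-1][1]

    def marginal_rate(self, taxable: float) -> float:
        """Federal marginal rate at a given taxable-income level."""
        rate = self.brackets[0][1]
        for lo, r in self.brackets:
            if taxable > lo or lo == 0.0:
                rate = r
        return rate


def _data_path() -> Path:
    return Path(str(resources.files("incomeshock") / "data" / "federal_tax_2023.yaml"))


def load_tax_schedule(
    path: str | Path | None = None,
    filing_status: str = "single",
    state_effective_rate: Optional[float] = None,
    deduction: float = 0.0,
) -> TaxSchedule:
    """Load a bracket schedule from YAML (default: packaged 2023 file).

    The file holds one or more named schedules under ``schedules`` (or a
    bare ``brackets`` list) plus a default ``state_effective_rate``.
    """
    raw = yaml.safe_load(Path(path or _data_path()).read_text())
    if "schedules" in raw:
        try:
            sched = raw["schedules"][filing_status]
        except KeyError:
            raise ValidationError(
                f"filing status {filing_status!r} not in schedule file"
            ) from None
        brackets = sched["brackets"]
    else:
        brackets = raw["brackets"]
    state = (
        state_effective_rate
        if state_effective_rate is not None
        else float(raw.get("state_effective_rate", 0.038))
    )
    return TaxSchedule(
        brackets=tuple((b["lower"], b["rate"]) for b in brackets),
        state_effective_rate=state,
        filing_status=filing_status,
        deduction=deduction,
    )


def default_schedule() -> TaxSchedule:
    """Packaged 2023 single-filer schedule with the 3.8% state rate."""
    return load_tax_schedule()


def federal_tax(gross: float, schedule: TaxSchedule) -> float:
    """Federal tax on a gross annual income under a bracket schedule.

    Sums each bracket's marginal rate times the portion of taxable
    income (gross minus the schedule's deduction, floored at 0) inside
    that bracket.
    """
    if gross < 0:
        raise ValueError(f"gross income must be >= 0, got {gross}")
    taxable = max(gross - schedule.deduction, 0.0)
    tax = 0.0
    lowers = [lo for lo, _ in schedule.brackets] + [float("inf")]
    for (lo, rate), hi in zip(schedule.brackets, lowers[1:]):
        if taxable <= lo:
            break
        tax += rate * (min(taxable, hi) - lo)
    return tax


def after_tax_income(gross: float, schedule: TaxSchedule) -> float:
    """Net annual income: gross minus federal tax minus flat state tax."""
    if gross < 0:
        raise ValueError(f"gross income must be >= 0, got {gross}")
    net = gross - federal_tax(gross, schedule) - schedule.state_effective_rate * gross
    return max(net, 0.0)


def apply_taxes(cohort: Cohort, schedule: Optional[TaxSchedule] = None) -> Cohort:
    """Populate ``after_tax_income`` on every household in a cohort."""
    schedule = schedule or default_schedule()
    out = []
    for rec in cohort:
        try:
            out.append(with_after_tax(rec, after_tax_income(rec.gross_income, schedule)))
        except ValueError as exc:
            raise ValidationError(f"household {rec.id!r}: {exc}") from exc
    return Cohort(records=tuple(out), provenance=cohort.provenance)
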