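"""Synthetic cohorts and disability hazard tables.

Real inputs for this kind of analysis are restricted-use or
download-only: a national household finance survey (incomes, savings,
housing costs) and actuarial disability tables. This module generates
stand-ins with controllable, documented distributions so the whole
pipeline is testable offline:

* gross income log-normal (right-skewed, as household income is);
* liquid savings expressed in *months of housing cost* held, drawn
  exponentially — which makes time-to-insolvency directly controllable
  in tests;
* retirement savings as an exponential multiple of annual income;
* housing cost as a normal share of monthly gross income, clipped to
  [0, 1];
* ages uniform over the modeled range, two genders by a split fraction.

The hazard generator produces a geometric age-ramp of annual disability
probabilities with a male/female ratio and can rescale the whole table
so the implied cumulative disability probability from the youngest
modeled age to the terminal age hits a calibration target (the
published benchmark is a 25% lifetime probability of full disability).

Defaults are plausible-population placeholders, not estimates fitted to
any survey. All generation is reproducible: one RNG stream keyed by the
seed, with a fixed per-household draw order (age, gender, income,
housing share, liquid-months, retirement-multiple) so appending a field
never reshuffles earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .actuarial import DisabilityTable
from .cohort import Cohort, Gender, HouseholdRecord
from .errors import ValidationError

__all__ = [
    "SyntheticCohortConfig",
    "HazardTableConfig",
    "generate_cohort",
    "generate_hazard_table",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of the synthetic household generator.

    ``income_log_mean``/``income_log_sd`` parameterize the log-normal
    gross income in log-USD; ``liquid_savings_months_mean`` is the mean
    number of months of housing cost held as liquid savings;
    ``retirement_multiple_mean`` the mean retirement balance as a
    multiple of annual gross income; ``housing_share_mean``/``_sd`` the
    normal share of monthly gross income spent on housing, clipped to
    [0, 1]; ``gender_split`` the fraction male.
    """

    n: int = 5718
    seed: int = 0
    income_log_mean: float = 11.0
    income_log_sd: float = 0.75
    liquid_savings_months_mean: float = 6.0
    retirement_multiple_mean: float = 1.5
    housing_share_mean: float = 0.25
    housing_share_sd: float = 0.10
    age_range: tuple[int, int] = (35, 64)
    gender_split: float = 0.512

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        for name in (
            "income_log_sd",
            "liquid_savings_months_mean",
            "retirement_multiple_mean",
            "housing_share_mean",
            "housing_share_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.gender_split <= 1.0:
            raise ValidationError("gender_split must be in [0, 1]")
        lo, hi = self.age_range
        if lo > hi:
            raise ValidationError("age_range must be (low, high) with low <= high")
        object.__setattr__(self, "age_range", (int(lo), int(hi)))

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        if "age_range" in d:
            d = {**d, "age_range": tuple(d["age_range"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        return d


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Draw ``config.n`` households; identical (config, seed) gives
    identical cohorts."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    records = []
    for i in range(config.n):
        age = int(rng.integers(lo, hi + 1))
        gender = Gender.MALE if rng.random() < config.gender_split else Gender.FEMALE
        gross = float(rng.lognormal(config.income_log_mean, config.income_log_sd))
        share = float(
            np.clip(rng.normal(config.housing_share_mean, config.housing_share_sd), 0.0, 1.0)
        )
        monthly_housing = share * gross / 12.0
        liquid_months = (
            float(rng.exponential(config.liquid_savings_months_mean))
            if config.liquid_savings_months_mean > 0
            else 0.0
        )
        retire_multiple = (
            float(rng.exponential(config.retirement_multiple_mean))
            if config.retirement_multiple_mean > 0
            else 0.0
        )
        records.append(
            HouseholdRecord(
                id=f"syn{i:06d}",
                age=age,
                gender=gender,
                gross_income=gross,
                liquid_savings=liquid_months * monthly_housing,
                retirement_savings=retire_multiple * gross,
                monthly_housing=monthly_housing,
            )
        )
    return Cohort(records=tuple(records), provenance=f"synthetic(seed={config.seed})")


@dataclass(frozen=True)
class HazardTableConfig:
    """Parameters of the synthetic disability hazard table.

    The female hazard at age ``a`` is ``base_hazard *
    age_slope**(a - age_min)``; the male hazard is ``gender_ratio``
    times that. When ``calibration_target`` is set, every hazard is
    rescaled by a common factor so the gender-averaged cumulative
    disability probability from ``age_min`` to ``terminal_age`` equals
    the target (to 1e-6).
    """

    base_hazard: float = 0.004
    age_slope: float = 1.06
    gender_ratio: float = 1.1
    calibration_target: Optional[float] = 0.25
    age_min: int = 35
    age_max: int = 64
    terminal_age: int = 65

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_hazard <= 1.0:
            raise ValidationError("base_hazard must be in [0, 1]")
        if self.age_slope < 1.0:
            raise ValidationError("age_slope must be >= 1")
        if self.gender_ratio <= 0:
            raise ValidationError("gender_ratio must be > 0")
        if self.calibration_target is not None and not 0.0 < self.calibration_target < 1.0:
            raise ValidationError("calibration_target must be in (0, 1)")
        if self.age_min > self.age_max or self.age_max >= self.terminal_age:
            raise ValidationError("require age_min <= age_max < terminal_age")

    @classmethod
    def from_dict(cls, d: dict) -> "HazardTableConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _raw_hazards(config: HazardTableConfig) -> dict[tuple[int, Gender], float]:
    out = {}
    for age in range(config.age_min, config.age_max + 1):
        female = config.base_hazard * config.age_slope ** (age - config.age_min)
        male = config.gender_ratio * female
        if female > 1.0 or male > 1.0:
            raise ValidationError(
                f"hazard parameters produce probability > 1 at age {age}"
            )
        out[(age, Gender.FEMALE)] = female
        out[(age, Gender.MALE)] = male
    return out


def _cumulative_from_youngest(
    hazards: dict[tuple[int, Gender], float], config: HazardTableConfig, scale: float
) -> float:
    """Gender-averaged cumulative disability probability from age_min to
    the terminal age, with all hazards scaled by ``scale``."""
    cums = []
    for gender in (Gender.MALE, Gender.FEMALE):
        surv = 1.0
        for age in range(config.age_min, config.terminal_age):
            h = hazards[(min(age, config.age_max), gender)] * scale
            surv *= 1.0 - min(h, 1.0)
        cums.append(1.0 - surv)
    return float(np.mean(cums))


def generate_hazard_table(config: HazardTableConfig) -> DisabilityTable:
    """Build (and optionally calibrate) a synthetic hazard table.

    Hazards rise geometrically with age and differ by gender; ages past
    ``age_max`` up to the terminal age reuse the ``age_max`` hazard in
    the calibration product.
    """
    hazards = _raw_hazards(config)
    scale = 1.0
    if config.calibration_target is not None and config.base_hazard > 0:
        target = config.calibration_target

        def gap(s: float) -> float:
            return _cumulative_from_youngest(hazards, config, s) - target

        hi = 1.0
        while gap(hi) < 0 and hi < 1e9:
            hi *= 2.0
        scale = float(brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16))
    entries = {k: min(h * scale, 1.0) for k, h in hazards.items()}
    return DisabilityTable(entries=entries, terminal_age=config.terminal_age)
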