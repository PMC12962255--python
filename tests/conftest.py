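import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from incomeshock import (
    Cohort,
    Gender,
    HouseholdRecord,
    SyntheticCohortConfig,
    apply_taxes,
    default_schedule,
    generate_cohort,
)


def per_dollar_federal_tax(gross: float, schedule) -> float:
    """Independent oracle: sum the marginal rate over each whole dollar.

    Dollar d (spanning taxable income (d-1, d]) is taxed at the rate of
    the bracket containing it. Ignores the fractional last dollar, so it
    agrees with the bracket formula to within $1.
    """
    taxable = max(gross - schedule.deduction, 0.0)
    n = int(np.floor(taxable))
    if n == 0:
        return 0.0
    # dollar d spans taxable income (d-1, d]; its rate is the bracket
    # containing the midpoint d-0.5 (bounds are whole dollars)
    midpoints = np.arange(1, n + 1, dtype=np.float64) - 0.5
    lowers = np.array([lo for lo, _ in schedule.brackets])
    rates = np.array([r for _, r in schedule.brackets])
    idx = np.searchsorted(lowers, midpoints, side="right") - 1
    return float(rates[idx].sum())


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture
def small_cohort():
    recs = (
        HouseholdRecord("a", 40, Gender.MALE, 60_000, 9_000, 30_000, 1_500),
        HouseholdRecord("b", 55, Gender.FEMALE, 120_000, 2_000, 80_000, 2_500),
        HouseholdRecord("c", 64, Gender.FEMALE, 30_000, 0, 0, 1_000),
    )
    return Cohort(records=recs, provenance="fixture")


@pytest.fixture(scope="session")
def taxed_synthetic_cohort():
    cohort = generate_cohort(SyntheticCohortConfig(n=1000, seed=42))
    return apply_taxes(cohort)
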