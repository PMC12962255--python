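import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from incomeshock import (
    DEFAULT_POPULATION_35_64,
    DisabilityTable,
    Gender,
    HouseholdRecord,
    aggregate_premiums,
    cumulative_disability_prob,
    expected_wealth,
    fair_premium,
    load_hazard_table,
    price_household,
    save_hazard_table,
)
from incomeshock.actuarial import PremiumResult, premium_frame
from incomeshock.errors import LookupError_, ValidationError

# Worked reference case: a 55-64-year-old with $87,500 after-tax income,
# 0.165 cumulative disability probability, $17,868 average SSDI benefit.
REF_INCOME = 87_500.0
REF_PRB = 0.165
REF_SSDI = 17_868.0


def constant_table(h, ages=range(35, 65)):
    return DisabilityTable(
        entries={(a, g): h for a in ages for g in Gender}, terminal_age=65
    )


class TestCumulativeDisability:
    def test_zero_hazard(self):
        assert cumulative_disability_prob(40, Gender.MALE, constant_table(0.0)) == 0.0

    def test_single_year(self):
        t = constant_table(0.07, ages=[64])
        assert cumulative_disability_prob(64, Gender.FEMALE, t) == pytest.approx(0.07)

    def test_constant_hazard_product(self):
        t = constant_table(0.01)
        assert cumulative_disability_prob(55, Gender.MALE, t) == pytest.approx(
            1 - 0.99**10
        )

    def test_non_increasing_in_age(self):
        t = constant_table(0.02)
        probs = [cumulative_disability_prob(a, Gender.MALE, t) for a in range(35, 65)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_missing_age_raises(self):
        with pytest.raises(LookupError_):
            cumulative_disability_prob(30, Gender.MALE, constant_table(0.01))


class TestExpectedWealthAndPremium:
    def test_reference_expected_wealth_no_benefits(self):
        assert expected_wealth(REF_INCOME, REF_PRB, 0.0) == pytest.approx(73_062.50)

    def test_reference_expected_wealth_with_ssdi(self):
        assert expected_wealth(REF_INCOME, REF_PRB, REF_SSDI) == pytest.approx(76_010.72)

    def test_certainty_case(self):
        assert expected_wealth(1234.0, 0.0, 0.0) == 1234.0

    def test_reference_premiums(self):
        assert fair_premium(REF_INCOME, 73_062.50) == pytest.approx(14_437.50)
        assert fair_premium(REF_INCOME, 76_010.72) == pytest.approx(11_489.28)

    def test_no_risk_no_premium(self):
        assert fair_premium(50_000, 50_000) == 0.0

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            expected_wealth(100, 1.5, 0)


class TestPriceHousehold:
    def make_record(self, net=REF_INCOME, age=60):
        return HouseholdRecord(
            "case35", age, Gender.MALE, net, 0, 0, 0, after_tax_income=net
        )

    def test_reference_case_end_to_end(self):
        res = price_household(self.make_record(), prb_override=REF_PRB)
        assert res.premium_no_ssdi == pytest.approx(14_437, abs=1)
        assert res.premium_ssdi == pytest.approx(11_490, abs=1)
        assert res.expected_wealth_no_ssdi == pytest.approx(73_063, abs=1)
        assert res.expected_wealth_ssdi == pytest.approx(76_010, abs=1)
        assert res.Prg + res.Prb == pytest.approx(1.0, abs=1e-12)
        assert res.Wb == 0.0

    def test_zero_probability_zero_premiums(self):
        res = price_household(self.make_record(), prb_override=0.0)
        assert res.premium_no_ssdi == 0.0
        assert res.premium_ssdi == 0.0

    def test_table_lookup_path(self):
        res = price_household(self.make_record(age=55), table=constant_table(0.01))
        assert res.Prb == pytest.approx(1 - 0.99**10)

    @settings(max_examples=200, deadline=None)
    @given(
        net=st.floats(REF_SSDI, 5e5),
        prb=st.floats(0, 1),
        ssdi=st.floats(0, REF_SSDI),
    )
    def test_premium_identity(self, net, prb, ssdi):
        """Fair premium reduces algebraically to Prb x (income - benefit)."""
        res = price_household(self.make_record(net=net), prb_override=prb, ssdi_benefit=ssdi)
        assert res.premium_no_ssdi == pytest.approx(prb * net, rel=1e-9, abs=1e-9)
        assert res.premium_ssdi == pytest.approx(prb * (net - ssdi), rel=1e-9, abs=1e-9)
        assert res.premium_ssdi <= res.premium_no_ssdi + 1e-9


class TestAggregation:
    def make_results(self, premiums):
        return [
            PremiumResult(
                household_id=str(i), age=50, gender=Gender.MALE, Wg=p, Prg=0.9,
                Wb=0, Wb_SSDI=0, Prb=0.1,
                expected_wealth_no_ssdi=0, expected_wealth_ssdi=0,
                premium_no_ssdi=p, premium_ssdi=p / 2,
            )
            for i, p in enumerate(premiums)
        ]

    def test_identity_scaling(self):
        agg = aggregate_premiums(self.make_results([100.0]), population_size=1)
        assert agg.scale_multiple == 1
        assert agg.scaled_total_no_ssdi == 100.0

    def test_census_scale_multiple(self):
        results = self.make_results([0.0] * 5718)
        agg = aggregate_premiums(results, population_size=DEFAULT_POPULATION_35_64)
        assert agg.scale_multiple == 22_150
        assert agg.scaled_total_no_ssdi == 0.0

    def test_linearity(self):
        base = aggregate_premiums(self.make_results([10, 20, 30]), population_size=300)
        tripled = aggregate_premiums(self.make_results([30, 60, 90]), population_size=300)
        assert tripled.scaled_total_no_ssdi == pytest.approx(3 * base.scaled_total_no_ssdi)
        assert tripled.scaled_total_ssdi == pytest.approx(3 * base.scaled_total_ssdi)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_premiums([], population_size=100)


class TestHazardTableIO:
    def test_round_trip(self, tmp_path):
        t = constant_table(0.015)
        loaded = load_hazard_table(save_hazard_table(t, tmp_path / "h.csv"))
        assert loaded.entries == t.entries

    def test_bad_hazard_rejected(self):
        with pytest.raises(ValidationError):
            constant_table(1.5)


def test_premium_frame_columns():
    res = price_household(
        HouseholdRecord("x", 50, Gender.FEMALE, 1000, 0, 0, 0, after_tax_income=1000),
        prb_override=0.1,
    )
    df = premium_frame([res])
    assert list(df.columns) == [
        "id", "age", "gender", "Wg", "Prb", "premium_no_ssdi", "premium_ssdi",
    ]
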