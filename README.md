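# incomeshock

Household income-shock stress testing and actuarially fair catastrophic
income-loss insurance premiums.

Treatment for serious illness — the motivating case is head and neck
cancer, where surgery plus adjuvant therapy removes a patient from work
for three months or more — cuts off household income while expenses
continue. This package answers two questions about that shock at
population scale:

1. **How fast do households become insolvent?** Each household's monthly
   cash flow is simulated: it starts from an accessible-savings buffer,
   receives a fraction of its after-tax income each month, and pays its
   monthly housing cost (the one expense modeled). A household is
   insolvent the first month its balance falls below zero. Three
   standard scenarios are compared: total income loss with only liquid
   savings, a 50% income reduction, and total income loss with
   retirement savings liquidatable.
2. **What would insuring the income cost?** For a household of age *a*
   the probability of full disability before age 65 is cumulated from
   annual hazards *h(t, gender)*:

   *Prb(a)* = 1 − ∏<sub>t=a</sub><sup>64</sup> (1 − *h(t, g)*)

   With one year's after-tax income *W<sub>g</sub>* at stake, expected
   wealth is *W<sub>g</sub>*(1 − *Prb*) + *W<sub>b</sub>·Prb*, and the
   actuarially fair annual premium is income minus expected wealth —
   which simplifies to *Prb·W<sub>g</sub>* without benefits and
   *Prb·(W<sub>g</sub> − W<sub>SSDI</sub>)* when an average SSDI benefit
   ($17,868/yr) offsets the disabled state. Per-household premiums are
   summed and scaled to the 126.7M US residents aged 35–64.

Gross income becomes after-tax income through the 2023 US federal
bracket schedule plus a flat 3.8% effective state rate. A synthetic
cohort generator (log-normal incomes, savings in months-of-housing,
housing as a share of income) and a calibrated synthetic disability
hazard table make the whole pipeline runnable offline; real survey
extracts load through a column-mapping adapter.

## Worked example

```python
import incomeshock as isk

# One respondent: $87,500 after-tax income, disability probability 0.165
rec = isk.HouseholdRecord("case35", 60, isk.Gender.MALE, 87_500, 0, 0, 0,
                          after_tax_income=87_500.0)
res = isk.price_household(rec, prb_override=0.165)
print(f"premium without SSDI: ${res.premium_no_ssdi:,.0f}")
print(f"premium with SSDI:    ${res.premium_ssdi:,.0f}")

# A synthetic 2,000-household cohort through the whole pipeline
cohort = isk.apply_taxes(isk.generate_cohort(isk.SyntheticCohortConfig(n=2000, seed=1)))
for c in isk.run_stress_suite(cohort):
    print(c.scenario, f"month 3: {100*c.rate_at(3):.1f}%  month 6: {100*c.rate_at(6):.1f}%")

table = isk.generate_hazard_table(isk.HazardTableConfig())
agg = isk.aggregate_premiums(isk.price_cohort(cohort, table),
                             population_size=isk.DEFAULT_POPULATION_35_64)
print(f"scale multiple: {agg.scale_multiple:,}")
print(f"aggregate premium (no SSDI): ${agg.scaled_total_no_ssdi:,.0f}")
```

prints

```
premium without SSDI: $14,438
premium with SSDI:    $11,489
test1_no_income month 3: 39.2%  month 6: 62.2%
test2_half_income month 3: 0.2%  month 6: 0.6%
test3_liquidate_retirement month 3: 0.9%  month 6: 2.7%
scale multiple: 63,326
aggregate premium (no SSDI): $1,266,468,555,768
```

The single-respondent premiums are the expected annual loss with and
without the SSDI offset (0.165 × $87,500 and 0.165 × ($87,500 −
$17,868)). The insolvency lines show the cumulative share of the
synthetic cohort unable to cover housing by months 3 and 6 under each
scenario — total income loss bites hard and early, while half income or
retirement access keeps most households solvent over six months. The
scale multiple is the US 35–64 population divided by the cohort size,
and the aggregate is the fair premium bill if every such household
participated. Synthetic-cohort magnitudes reflect the generator's
placeholder distributions, not any real survey (see
`docs/methods.md`).

The same pipeline runs from a shell:

```bash
incomeshock all --out runs/demo --seed 1
incomeshock premiums --cohort mysurvey.csv --hazard ssa_table.csv \
    --out runs/real --column-map '{"gross_income": "hh_income"}'
```

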