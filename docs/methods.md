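# Methods

## Model overview

The package links three small models end to end.

**Tax conversion.** After-tax income is gross income minus progressive
federal tax minus a flat effective state tax. Federal tax sums each
bracket's marginal rate over the slice of income inside the bracket;
the packaged schedule is the 2023 US single-filer schedule, with a
married-joint alternative in the same data file. Brackets apply to
gross income directly: no standard deduction or credits are assumed
(a `deduction` field, default 0, exists for sensitivity analysis), and
the 3.8% state rate is applied to gross income as a flat share rather
than to federal taxable income — it is an *effective* rate standing in
for heterogeneous state schedules. Payroll (FICA) taxes are out of
scope.

**Cash-flow stress test.** Each household enters a scenario with an
opening balance equal to the savings tier the scenario grants
(`none`, `liquid`, or `liquid_plus_retirement`), then for each month
*m* of the horizon the balance is

    balance(m) = opening + m * (income_fraction * net_income / 12 - monthly_housing)

computed in closed form per month so no rounding accumulates. Housing
is the only expense, constant over the horizon; the income reduction
persists for the whole horizon (6 months by default) rather than only
the first three, so 6-month insolvency rates describe an unrelieved
shock. Insolvency is a strictly negative balance after paying the
month's housing — a balance of exactly zero still covers the month —
and is absorbing. With zero income this yields the closed form
`first_insolvent_month = floor(savings / housing) + 1`, which the test
suite checks exactly. Cohort curves are weight-averaged cumulative
insolvency fractions and are therefore monotone in month and bounded in
[0, 1]; enlarging savings access or retained income can never raise
them (pointwise dominance, also tested).

The three standard scenarios are: (1) no income, liquid savings only;
(2) 50% income, liquid savings; (3) no income, liquid plus retirement
savings. Households that cannot liquidate retirement funds still use
their liquid tier — if scenarios 1–2 allowed no buffer at all, every
household with positive housing cost would be insolvent at month 1 and
the comparison across scenarios would collapse. Retirement liquidation
is penalty-free by default; a `retirement_haircut` fraction (default 0)
can model early-withdrawal penalties, which real households would
likely face.

**Actuarially fair premium.** A two-state, one-year lottery per
household: well with probability `Prg`, disabled with probability
`Prb`, wealth one year of after-tax income in the well state and 0 (or
the average annual SSDI benefit, $17,868) in the disabled state. `Prb`
is the cumulative probability of becoming disabled between the
household's age and the terminal age 65, computed as the complement of
surviving every annual hazard. The fair premium is income minus
expected wealth, algebraically `Prb * income` without benefits and
`Prb * (income - benefit)` with them; the test suite verifies this
identity to 1e-9. Premiums are summed (survey-weighted if weights are
present) and scaled by `round(population / respondents)`; with the
2023 Census estimate of 126,651,558 US residents aged 35–64 and 5,718
respondents the multiple is 22,150. Pricing is risk-neutral with full
participation and no loading factor (a configurable multiplier, default
1, is available); utility-based risk-averse pricing and adverse
selection are out of scope. "Wealth" is one year's income with no
multi-year discounting.

How a published cumulative disability probability was derived from
annual actuarial tables is generally not recoverable, so
`price_household` accepts a direct `Prb` override; the worked
single-respondent example (Prb = 0.165) is reproduced through the
override path.

## Synthetic data

The generator emulates a national household-finance survey extract in
shape, not in fitted values:

| parameter | default | meaning |
|---|---|---|
| `n` | 5718 | households (a typical in-scope respondent count) |
| `income_log_mean`, `income_log_sd` | 11.0, 0.75 | log-normal gross income (median ≈ $60k, right-skewed) |
| `housing_share_mean`, `housing_share_sd` | 0.25, 0.10 | normal housing share of gross income, clipped to [0, 1] |
| `liquid_savings_months_mean` | 6.0 | exponential months of housing cost held liquid |
| `retirement_multiple_mean` | 1.5 | exponential retirement balance as a multiple of income |
| `age_range` | (35, 64) | uniform ages, the at-risk working window |
| `gender_split` | 0.512 | fraction male |

Liquid savings are parameterized in months of housing cost because
that makes time-to-insolvency directly controllable: a household
holding *k* months becomes insolvent at month `floor(k) + 1` under
total income loss. One RNG stream keyed by the seed draws per household
in a fixed order (age, gender, income, housing share, liquid months,
retirement multiple), so adding a field appends draws without
reshuffling existing fixtures; identical configs give byte-identical
CSVs.

What the generator does **not** emulate: the joint correlation
structure of income, savings, and housing in real surveys (draws are
conditionally independent given income); categorical/bracketed income
reporting; survey weights (all 1 by default); non-housing expenses.
Passing tests on synthetic cohorts therefore validate the machinery —
monotonicity, closed forms, determinism, accounting identities — not
the empirical insolvency rates of any real population, and
synthetic-cohort rates should not be read as estimates of published
survey-based results. Real extracts enter through
`load_cohort(column_map=...)`, which also splits a single combined
savings figure into liquid/retirement tiers by a configurable fraction
(default 0.5), since combined-savings surveys do not observe the split.

The synthetic hazard table uses a geometric age ramp
`h(a) = base * slope^(a-35)` for females, times a male/female ratio
(default 1.1) for males, and rescales all hazards by one common factor
so the gender-averaged cumulative disability probability from age 35 to
65 matches a calibration target (default 0.25, the published benchmark
for lifetime disability risk — quoted for a 20-year-old, applied here
to the youngest modeled age since ages under 35 are outside the table;
given that serious disability is rare before 35, this overstates
hazards 35–64 slightly). The rescaling factor is found by bisection
(`scipy.optimize.brentq`) to machine precision; the calibration
invariant is tested at 1e-6. A real actuarial table can be supplied as
a CSV (`age,gender,annual_hazard`) instead.

## Numerical choices

- All money arithmetic is double precision; rounding happens only at
  reporting. The worked example's printed cells land on exact half
  dollars (e.g. $14,437.50), so reproduction is asserted at ±$1 rather
  than enforcing a rounding rule.
- Monthly balances are computed as `opening + m * delta`, not by
  accumulation, so the closed-form insolvency month holds exactly for
  integer-dollar inputs.
- Balance exactly 0 is solvent; `Prb` exactly 0 or 1 is accepted;
  empty cohorts are an error for rate computations (the rate is
  undefined) but fine for I/O.
- The scale multiple rounds to the nearest integer, matching the
  convention of published population multiples.
- Age bounds of the eligibility filter are inclusive on both ends;
  ages are stored in integer years and 10-year bands are derived on
  demand (the hazard lookup needs exact ages; bands are derivable, ages
  are not).

## Problem sizes

The test suite runs cohorts up to 10,000 households and property
checks at 1,000 random inputs; the acceptance script uses a
5,718-household cohort. At these sizes the full pipeline completes in
seconds.

## Known limitations

- Housing is the only expense; food, transport, debt service, and
  medical cost sharing are unmodeled, so simulated insolvency rates are
  a lower bound for any real cohort.
- No borrowing, home equity access, or spending adjustment over time.
- One-year, risk-neutral insurance pricing; no discounting, loading,
  or participation modeling.
- The tax engine omits deductions, credits, and payroll taxes by
  design; filing status is uniform per run.
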