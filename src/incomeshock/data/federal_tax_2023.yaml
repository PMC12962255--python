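# US federal income tax brackets, tax year 2023.
# Each bracket: lower bound of taxable income (USD) and the marginal rate
# applied to income above that bound (up to the next bracket's bound).
state_effective_rate: 0.038
schedules:
  single:
    brackets:
      - {lower: 0, rate: 0.10}
      - {lower: 11000, rate: 0.12}
      - {lower: 44725, rate: 0.22}
      - {lower: 95375, rate: 0.24}
      - {lower: 182100, rate: 0.32}
      - {lower: 231250, rate: 0.35}
      - {lower: 578125, rate: 0.37}
  married_joint:
    brackets:
      - {lower: 0, rate: 0.10}
      - {lower: 22000, rate: 0.12}
      - {lower: 89450, rate: 0.22}
      - {lower: 190750, rate: 0.24}
      - {lower: 364200, rate: 0.32}
      - {lower: 462500, rate: 0.35}
      - {lower: 693750, rate: 0.37}
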