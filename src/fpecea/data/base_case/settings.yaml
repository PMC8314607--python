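# Model settings for the German fall-prevention exercise cost-effectiveness model.
sex: women
entry_age: 75
horizon_years: 25
cycle_length_months: 6
# 3%/year on costs and outcome counts (German guideline convention)
discount_rate: 0.03
discount_outcomes: true
half_cycle_correction: false
use_late_first_fracture: false
effect:
  rr: 0.73
  rr_low: 0.56
  rr_high: 0.95
  participation_rate: 0.7
  annual_decay_fraction: 0.28
  effect_zero_after_years: 4
tables:
  clinical: clinical.csv
  costs: costs.csv
  intervention: intervention_costs.csv
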