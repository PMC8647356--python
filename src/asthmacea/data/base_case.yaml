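p_controlled_to_ocs_burst:
  base: 0.11
  low: 0.1
  high: 0.14
p_ocs_burst_to_ed:
  base: 0.02
  low: 0.02
  high: 0.03
p_ed_to_hospitalization:
  base: 0.0117
  low: 0.008775
  high: 0.014625
p_hospitalization_to_asthma_death:
  base: 2.0e-06
  low: 1.5e-06
  high: 2.4999999999999998e-06
u_controlled:
  base: 0.92
  low: 0.69
  high: 1.0
u_ocs_burst:
  base: 0.86
  low: 0.65
  high: 1.0
u_ed_visit:
  base: 0.83
  low: 0.62
  high: 1.0
u_hospitalization:
  base: 0.74
  low: 0.56
  high: 0.93
drug_cost_per_120_doses:
  base: 53.0
  low: 40.0
  high: 66.0
annual_cost_controlled:
  base: 416.0
  low: 312.0
  high: 520.0
cost_mild_exacerbation:
  base: 94.0
  low: 71.0
  high: 118.0
cost_moderate_exacerbation:
  base: 191.0
  low: 143.0
  high: 239.0
cost_severe_exacerbation:
  base: 386.0
  low: 290.0
  high: 483.0
rr_exacerbation:
  base: 0.85
  low: 0.72
  high: 1.0
or_ed_visit:
  base: 0.65
  low: 0.43
  high: 0.98
adherence_as_needed:
  base: 0.68
  low: 0.51
  high: 0.85
adherence_maintenance:
  base: 0.62
  low: 0.47
  high: 0.78
as_needed_doses_per_day:
  base: 0.52
  low: 0.39
  high: 0.65
annual_discount_rate:
  base: 0.05
  low: 0.0
  high: 0.06
cycle_length_days: 28
starting_age_years: 30
horizon_age_years: 100
half_cycle_correction: true
wtp_per_qaly: 19000.0
psa_iterations: 1000
rng_seed: 2021
ed_effect_scale: odds
adherence_scales_effect: false
efs_landmark_years: 1.0
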