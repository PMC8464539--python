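# Base-case parameterization: suspected-stroke CTA cohort (UK, 2019 USD).
# Flat schema: every key is a model field; omit a key to use the built-in
# default (this file spells out all of them). Unknown keys are rejected.
# mrs_* vectors are probabilities over mRS 0-5 and death; *_by_state vectors
# are per-mRS values (acute costs include a death-state entry).
acute_by_state:
- 4350.0
- 5117.0
- 5885.0
- 22695.0
- 30704.0
- 36468.0
- 4603.0
acute_year_fraction: 0.2464065708418891
age0: 66
ai_per_analysis: 40.0
cohort_n: 71840
cycles: 70
discount_costs: 0.04
discount_utilities: 0.015
fp_cost_per_point: 0.0
fp_rate_points: 0.0
longterm_by_state:
- 3936.0
- 4631.0
- 5325.0
- 18944.0
- 25631.0
- 41621.0
mrs_iat:
- 0.11
- 0.18
- 0.2
- 0.17
- 0.16
- 0.04
- 0.14
mrs_no_iat:
- 0.05
- 0.08
- 0.11
- 0.17
- 0.27
- 0.12
- 0.2
non_lvo_profile: healthy
p_eligible: 0.438
p_lvo: 0.306
p_missed: 0.06
p_recurrent: 0.0284
recurrence_acute_costs: false
recurrence_rule: clamp_max
reduction: 0.5
seed: 0
tx_iat: 11728.0
tx_no_iat: 1004.0
utility_by_state:
- 0.95
- 0.93
- 0.83
- 0.62
- 0.42
- 0.11
wtp_per_qaly: 25662.0
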