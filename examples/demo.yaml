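# Demo: simulate a waitlist trial under the default study conditions and
# run the full analysis chain.  All outputs are deterministic given `seed`.
seed: 1

simulation:
  n_intervention: 89
  n_waitlist: 90
  retention: [179, 149, 134, 118]
  complete_case_target: 104
  item_missing_rate: 0.0055

analysis:
  lambda_base: 500000
  lambda_max: 1000000
  discount_rate: 0.03
  users_per_year: 988
  horizon_years: 5
  app_cost_per_user: 12

output: waitcea_out
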