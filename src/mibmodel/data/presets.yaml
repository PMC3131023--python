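# Succession-model parameter presets for the five degraded-area types.
# "unverified" lists parameters whose value could not be confirmed from
# field data (too few young or old stands); model plots dash the
# corresponding curve segments.
forest_soil_planted:
  initial_level_mg: 40.0
  delay_years: 0.0
  increase_rate_per_year: 0.18
  recovery_level_mg: 290.0
  unverified: [n0, t_delay, r]
post_agri_natural:
  initial_level_mg: 40.0
  delay_years: 0.0
  increase_rate_per_year: 0.18
  recovery_level_mg: 250.0
  unverified: []
post_agri_planted:
  initial_level_mg: 40.0
  delay_years: 0.0
  increase_rate_per_year: 0.5
  recovery_level_mg: 250.0
  unverified: []
ash_heap:
  initial_level_mg: 40.0
  delay_years: 10.0
  increase_rate_per_year: 0.28
  recovery_level_mg: 210.0
  unverified: [t_delay, r, k]
mining_heap:
  initial_level_mg: 40.0
  delay_years: 10.0
  increase_rate_per_year: 0.6
  recovery_level_mg: 210.0
  unverified: []
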