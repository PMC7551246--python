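# Default run configuration: a 25-province synthetic world with the
# standard scenario grid (25%/75% coverage x delivery types 1/2).
sim:
  n_provinces: 25
  children_per_province: 400
  seed: 0

effect:
  eff_cm: 2.46
  ci_lower_cm: 0.96
  ci_upper_cm: 3.97

costs:
  m_cents: 35.0
  f_cents: 17.9
  a_cents: 16.7
  tv_cents: 0.9
  tm_max_cents: 13.5
  tm_min_cents: 0.9
  r_min: 31.0
  r_max: 208.0
  packs_per_year: 365
  trips_per_year: 12
  hours_per_workyear: 2000.0

scenarios:
  - {coverage: 0.25, delivery_type: 1}
  - {coverage: 0.25, delivery_type: 2}
  - {coverage: 0.75, delivery_type: 1}
  - {coverage: 0.75, delivery_type: 2}

out_dir: results
log_level: INFO
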