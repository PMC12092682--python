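# Example end-to-end pipeline configuration for `bcpipe run`.
# mode: synthetic generates a cohort; mode: ingest reads the tables
# listed under inputs: (clinical/somatic/germline/panel paths).
mode: synthetic
feature_kind: gene
cohort:
  n_per_group: {EUR: 500, AFR: 120, SAS: 110, Admix: 60}
  seed: 0
power:
  frequencies: [0.05, 0.25]
  alpha: 0.1
  target_power: 0.9
  n_sims: 20000
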