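# Demo run: synthetic kidney-disease cohort with five planted features.
complication: kidney
synthetic:
  n_patients: 1000
  n_planted: 5
  p_fast: 0.8
  p_slow: 0.4
  n_background: 40
  background_prevalence: 0.15
pipeline:
  alpha: 0.05
  n_max: 12
  repeats: 5
  n_grid: [7, 10, 12, 15, 17, 20]
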