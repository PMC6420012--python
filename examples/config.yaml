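# Example nadflux pipeline configuration.
calibration:
  min_r_squared: 0.99
  weighting: null          # or "1/x"
  loq_pmol:
    d0-NAD+: 0.4
    d3-NAD+: 0.4
    d0-Nam: 0.1
    d3-Nam: 0.1
    d4-Nam: 0.1

validation:
  recycling_threshold: 0.10
  linearity_min_r_squared: 0.98
  equivalence_tolerance: 0.15

simulation:
  nam_medium0: 2.0         # uM d4-Nam at the medium switch
  noise_cv: 0.05
  seed: 0
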