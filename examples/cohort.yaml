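# Synthetic 15-patient cohort, balanced across the three stem archetypes.
cohort:
  n: 15
  seed: 42        # mandatory: cohorts are pure functions of their seed
  noise_rate: 0.1 # class-uniform label flips on the synthetic observations
simulation:
  max_element_area: 3.0
calibration:
  grid: [3.0, 25.0, 0.25]  # J/kg
  t_low: 2.0               # omit to estimate from resorption-zone IQR
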