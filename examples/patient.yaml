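# Single-patient run: 70 kg, Pauwels angle 16 deg, neutral Proxima stem.
patient:
  id: DEMO-001
  body_weight: 70.0
  pauwels_angle: 16.0
  stem_type: proxima
  alignment_angle: 0.0
seed: 0
simulation:
  max_element_area: 2.0   # mm^2
  thickness: 10.0         # mm plane-stress slab
  band_width: 3.0         # mm bone-implant interface band
  thresholds: {low: 2.0, high: 12.0}
# geometry:               # optional FemurParams overrides (mm / deg)
#   ccd_angle: 130.0
# materials:
#   cancellous: {youngs_modulus: 800.0}
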