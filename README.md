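# femrem

Planar finite-element prediction of peri-implant bone remodeling around
short femoral stems, with mechanostat threshold calibration and a
stem-malposition sensitivity analysis.

The pipeline builds a parametric 2D frontal-plane model of a proximal femur
(cortical shell + cancellous interior), seats one of three short-stem
archetypes (a short lateral-flare stem, a slender curved neck-sparing stem,
and a longer triple-taper stem) in neutral, varus, or valgus alignment,
meshes the multi-material domain with constant-strain triangles, and solves
plane-stress linear elasticity under a physiological load case (joint
contact force of 2.38 x body weight at the head centre, tilted by the
patient's Pauwels angle, plus the abductor reaction at the greater
trochanter). Strain energy density in a band around the bone–implant
interface is converted to a mechanical stimulus (SED / cancellous bone
density, J/kg) and aggregated as an area-weighted median per modified Gruen
zone. A Frost-mechanostat rule classifies each zone as resorption
(stimulus < 2 J/kg), apposition (> 12 J/kg), or no activity (the lazy zone
in between); the upper threshold can be re-calibrated against observed zone
labels by exhaustive grid search, and the lower threshold estimated as the
first quartile of stimuli in resorption-labelled zones.

A synthetic-cohort module generates reproducible patients (body weight,
Pauwels angle, jittered geometry, stem assignment) and noisy "observed"
labels from a ground-truth mechanostat, enabling closed-loop testing
(parameter recovery) without any external data.

## Command-line interface

```sh
femrem run-patient     --config examples/patient.yaml --out out/patient
femrem simulate-cohort --config examples/cohort.yaml  --out out/cohort
femrem position-sweep  --config examples/patient.yaml --out out/sweep
femrem calibrate --zones out/cohort/pooled_zones.csv --t-low 2.0 --out out/cal.json
femrem stats     --zones out/cohort/pooled_zones.csv --out out/stats.json
```

Outputs: per-zone and per-element CSV tables (stamped with a config hash),
legacy-VTK meshes with SED/stimulus cell data, JSON reports, and PNG
figures. Exit codes: 0 success, 2 configuration error, 3 numerical failure.

## Notes on modelling choices

- The model is deliberately 2D plane stress (slab thickness 10 mm by
  default); the thickness is the main absolute-calibration knob for
  stimulus magnitudes and is exposed in the configuration.
- The stem is perfectly bonded to the bone (shared mesh nodes); the joint
  contact force is attached to the implant elements nearest the prosthetic
  head centre so that it is carried by the stem neck.
- Gruen zones are anatomical: zones 1–3 run proximal to distal on the
  lateral (trochanter) side, zone 4 is a one-stem-width band distal to the
  tip, zones 5–7 run distal to proximal on the medial side.
- All generators, the mesher, and the solver are deterministic; rerunning
  an unchanged configuration reproduces results byte for byte.
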