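# Per-orientation layer stacks for the 1D head surrogate (loaded face
# first) and gauge depths in millimetres into the brain layer.
# Thicknesses are conventional adult-anatomy defaults: the posterior
# skull is thicker than the anterior, and the temporal (lateral) skull
# is the thinnest.
anterior:
  layers:
    - {material: scalp, thickness: 5 mm}
    - {material: skull, thickness: 7 mm}
    - {material: csf, thickness: 3 mm}
    - {material: brain, thickness: 150 mm}
  brain_gauges_mm: [5, 25, 45, 65, 85, 105, 125, 145]
right_lateral:
  layers:
    - {material: scalp, thickness: 5 mm}
    - {material: skull, thickness: 4 mm}
    - {material: csf, thickness: 3 mm}
    - {material: brain, thickness: 150 mm}
  brain_gauges_mm: [5, 25, 45, 65, 85, 105, 125, 145]
posterior:
  layers:
    - {material: scalp, thickness: 5 mm}
    - {material: skull, thickness: 9 mm}
    - {material: csf, thickness: 3 mm}
    - {material: brain, thickness: 150 mm}
  brain_gauges_mm: [5, 25, 45, 65, 85, 105, 125, 145]
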