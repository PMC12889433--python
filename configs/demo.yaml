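# Shipped demo scenario: a small synthetic cohort with a genuine BAM2
# depletion, a Braak-linked fraction decline, one down-shifted metabolic
# subsystem in BAM2, and a 20% plaque-on-vessel image.
seed: 0
outdir: bamscape_demo
stages: [composition, metabolic, imaging]
synthetic:
  n_patients_per_condition: 20
  cells_per_patient_range: [300, 600]
  braak_fold_per_step: 1.25
  image_shape: [6, 192, 192]
  shift_map:
    SS00|BAM2: -0.5
metacell_size: 10
caa_targets: [0.2]
vessel_threshold: 100.0
plaque_threshold: 150.0
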