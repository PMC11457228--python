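# Girls cohort preset: template calibrated to published Korean reference
# means (takeoff 8.57 y at 5.10 cm/y; peak 8.32 cm/y at 10.99 y; spurt
# interval 3.72 y); tempo SD = reference APHV SD; velocity SD = reference
# PHV coefficient of variation; correlations from the reference
# random-effect correlation matrix; noise SD chosen so E|e| = 0.57 cm.
name: girls_gp2024
sex: female
template_targets:
  aogs: 8.57
  ogsv: 5.10
  aphv: 10.99
  phv: 8.32
  gsi: 3.72
  adult_height: 161.0
random_effect_sds: [5.0, 0.74, 0.1310]
random_effect_correlations:
  - [1.0, 0.18, 0.29]
  - [0.18, 1.0, -0.36]
  - [0.29, -0.36, 1.0]
noise_sd: 0.71
schedule: {start: 7.25, stop: 16.25, step: 0.5, jitter: 0.1}
missingness_prob: 0.30
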