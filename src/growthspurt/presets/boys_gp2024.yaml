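# Boys cohort preset: template calibrated to published Korean reference
# means (takeoff 10.17 y at 5.43 cm/y; peak 9.61 cm/y at 12.46 y; spurt
# interval 3.58 y); tempo SD = reference APHV SD; velocity SD = reference
# PHV coefficient of variation; correlations from the reference
# random-effect correlation matrix; noise SD chosen so E|e| = 0.62 cm.
name: boys_gp2024
sex: male
template_targets:
  aogs: 10.17
  ogsv: 5.43
  aphv: 12.46
  phv: 9.61
  gsi: 3.58
  adult_height: 174.0
random_effect_sds: [5.0, 0.69, 0.1311]
random_effect_correlations:
  - [1.0, 0.09, 0.33]
  - [0.09, 1.0, -0.43]
  - [0.33, -0.43, 1.0]
noise_sd: 0.78
schedule: {start: 7.25, stop: 16.25, step: 0.5, jitter: 0.1}
missingness_prob: 0.30
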