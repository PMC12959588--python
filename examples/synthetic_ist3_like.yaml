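n_patients: 3035
allocation_ratio: 0.5
treatment_main_effect: 0.1155
interaction_strength: -0.295
seed: 0
treatment_levels:
- Placebo
- Alteplase
outcome_coefficients:
  intercept: 5.3952
  age: -0.040821994520255166
  sex=Male: -0.020202707317519466
  lived_alone=No: -0.10536051565782628
  ischemic_change=Possibly yes: -0.020202707317519466
  ischemic_change=Definitely yes: -0.2613647641344075
  antiplatelet_48h=No: 0.02955880224154443
  atrial_fibrillation=No: 0.23901690047049992
  sbp: 0.0
  dbp: -0.005012541823544286
  weight: 0.009950330853168092
  gcs_eye=Spontaneously: 0.6830968447064438
  gcs_motor=Not normal: 0.0
  gcs_verbal=Noises only: -0.15082288973458366
  gcs_verbal=Inappropriate words: 0.494696241836107
  gcs_verbal=Confused: 0.01980262729617973
  gcs_verbal=Orientated: 0.34358970439007686
  gcs_total: -0.15082288973458366
  nihss: -0.18632957819149348
  stroke_subtype=PACI: 0.009950330853168092
  stroke_subtype=POCI: 0.10436001532424286
  stroke_subtype=TACI: -0.19845093872383832
covariate_spec:
- name: age
  kind: continuous
  distribution: normal
  params:
    mean: 78.0
    sd: 10.0
    low: 18.0
    high: 100.0
- name: sex
  kind: binary
  distribution: categorical
  params:
    levels:
    - Female
    - Male
    probs:
    - 0.519
    - 0.481
- name: lived_alone
  kind: binary
  distribution: categorical
  params:
    levels:
    - 'Yes'
    - 'No'
    probs:
    - 0.374
    - 0.626
- name: ischemic_change
  kind: categorical
  distribution: categorical
  params:
    levels:
    - 'No'
    - Possibly yes
    - Definitely yes
    probs:
    - 0.589
    - 0.232
    - 0.179
- name: antiplatelet_48h
  kind: binary
  distribution: categorical
  params:
    levels:
    - 'Yes'
    - 'No'
    probs:
    - 0.515
    - 0.485
- name: atrial_fibrillation
  kind: binary
  distribution: categorical
  params:
    levels:
    - 'Yes'
    - 'No'
    probs:
    - 0.302
    - 0.698
- name: sbp
  kind: continuous
  distribution: normal
  params:
    mean: 155.0
    sd: 22.2
    low: 70.0
    high: 260.0
- name: dbp
  kind: continuous
  distribution: normal
  params:
    mean: 81.0
    sd: 14.1
    low: 30.0
    high: 150.0
- name: weight
  kind: continuous
  distribution: normal
  params:
    mean: 71.0
    sd: 13.3
    low: 30.0
    high: 160.0
- name: gcs_eye
  kind: binary
  distribution: categorical
  params:
    levels:
    - Nonspontaneously
    - Spontaneously
    probs:
    - 0.147
    - 0.853
- name: gcs_motor
  kind: binary
  distribution: categorical
  params:
    levels:
    - Normal
    - Not normal
    probs:
    - 0.857
    - 0.143
- name: gcs_verbal
  kind: categorical
  distribution: categorical
  params:
    levels:
    - None
    - Noises only
    - Inappropriate words
    - Confused
    - Orientated
    probs:
    - 0.124
    - 0.113
    - 0.105
    - 0.127
    - 0.531
- name: gcs_total
  kind: continuous
  distribution: discrete
  params:
    values:
    - 3
    - 5
    - 7
    - 8
    - 9
    - 10
    - 11
    - 12
    - 13
    - 14
    - 15
    probs:
    - 0.005
    - 0.01
    - 0.02
    - 0.02
    - 0.03
    - 0.04
    - 0.06
    - 0.1
    - 0.165
    - 0.2
    - 0.35
- name: nihss
  kind: continuous
  distribution: gamma
  params:
    shape: 1.8
    scale: 7.1
    round: true
    low: 0.0
    high: 42.0
- name: stroke_subtype
  kind: categorical
  distribution: categorical
  params:
    levels:
    - LACI
    - PACI
    - POCI
    - TACI
    probs:
    - 0.109
    - 0.378
    - 0.081
    - 0.432
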