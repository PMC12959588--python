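variables:
- name: treatment
  kind: binary
  role: treatment
  levels:
  - Placebo
  - Alteplase
  reference: Placebo
- name: outcome
  kind: binary
  role: outcome
  levels:
  - '0'
  - '1'
  reference: '0'
- name: age
  kind: continuous
  role: predictor
- name: sex
  kind: binary
  role: predictor
  levels:
  - Female
  - Male
  reference: Female
- name: lived_alone
  kind: binary
  role: predictor
  levels:
  - 'Yes'
  - 'No'
  reference: 'Yes'
- name: ischemic_change
  kind: categorical
  role: predictor
  levels:
  - 'No'
  - Possibly yes
  - Definitely yes
  reference: 'No'
- name: antiplatelet_48h
  kind: binary
  role: predictor
  levels:
  - 'Yes'
  - 'No'
  reference: 'Yes'
- name: atrial_fibrillation
  kind: binary
  role: predictor
  levels:
  - 'Yes'
  - 'No'
  reference: 'Yes'
- name: sbp
  kind: continuous
  role: predictor
- name: dbp
  kind: continuous
  role: predictor
- name: weight
  kind: continuous
  role: predictor
- name: gcs_eye
  kind: binary
  role: predictor
  levels:
  - Nonspontaneously
  - Spontaneously
  reference: Nonspontaneously
- name: gcs_motor
  kind: binary
  role: predictor
  levels:
  - Normal
  - Not normal
  reference: Normal
- name: gcs_verbal
  kind: categorical
  role: predictor
  levels:
  - None
  - Noises only
  - Inappropriate words
  - Confused
  - Orientated
  reference: None
- name: gcs_total
  kind: continuous
  role: predictor
- name: nihss
  kind: continuous
  role: predictor
- name: stroke_subtype
  kind: categorical
  role: predictor
  levels:
  - LACI
  - PACI
  - POCI
  - TACI
  reference: LACI
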