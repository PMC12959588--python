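# Column-name mapping from a raw IST-3 dataset export to the schema names of
# examples/ist3_schema.yaml. The deposited dataset's field names are not
# printed in the summary publications, so the left-hand side below is a
# PLACEHOLDER the user must edit against the data dictionary that ships with
# the download (in particular the coding of the three Glasgow Coma Scale
# component variables). Values coded numerically in the raw file must first
# be recoded to the level strings the schema declares.
#
# usage: riskhte analyze --input ist3.csv --schema examples/ist3_schema.yaml \
#            --mapping examples/ist3_mapping.yaml
RAW_ID_FIELD: patient_id
RAW_TREATMENT_FIELD: treatment
RAW_OUTCOME_OHS6_FIELD: outcome
RAW_AGE_FIELD: age
RAW_SEX_FIELD: sex
RAW_LIVEALONE_FIELD: lived_alone
RAW_INFARCT_FIELD: ischemic_change
RAW_ANTIPLATELET_FIELD: antiplatelet_48h
RAW_ATRIALFIB_FIELD: atrial_fibrillation
RAW_SBP_FIELD: sbp
RAW_DBP_FIELD: dbp
RAW_WEIGHT_FIELD: weight
RAW_GCS_EYE_FIELD: gcs_eye
RAW_GCS_MOTOR_FIELD: gcs_motor
RAW_GCS_VERBAL_FIELD: gcs_verbal
RAW_GCS_TOTAL_FIELD: gcs_total
RAW_NIHSS_FIELD: nihss
RAW_STROKE_SUBTYPE_FIELD: stroke_subtype
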