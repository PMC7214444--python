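# Emulation map: losartan vs. placebo in type 2 diabetic nephropathy.
# SDs default to the table's sigma column. Triglycerides use a
# moment-matched lognormal (the printed sigma exceeds the mean, which a
# truncated normal cannot carry without distorting it). The urinary
# albumin:creatinine ratio is NED in the source column, so its recording
# probability is zero.
population:
  n_persons: 9545
  indication: {concept_id: C_DM_NEPHRO, prevalence: 0.4}

link_exclude: []

characteristics:
  - kind: demographic_category
    field: gender
    categories: {G_MALE: male, G_FEMALE: female, G_UNKNOWN: sex_unknown}
  - kind: demographic_category
    field: race
    categories:
      R_ASIAN: race_asian
      R_BLACK: race_black
      R_WHITE: race_white
      R_HISPANIC: race_hispanic
      R_OTHER: race_other
      R_UNKNOWN: race_unknown
  - row: age
    kind: age
    synth: {sd: 7.0}
  - row: bmi
    kind: measurement
    concept_id: M_BMI
    days_before: 365
    synth: {sd: 6.0, lower: 13, upper: 70}
  - row: sbp
    kind: measurement
    concept_id: M_SBP
    days_before: 365
    synth: {sd: 19.5, lower: 70, upper: 260}
  - row: dbp
    kind: measurement
    concept_id: M_DBP
    days_before: 365
    synth: {sd: 10.5, lower: 35, upper: 140}
  - row: map
    kind: measurement
    concept_id: M_MAP
    days_before: 365
    synth: {sd: 11.25, lower: 50, upper: 180}
  - row: pulse
    kind: measurement
    concept_id: M_PULSE
    days_before: 365
    synth: {sd: 17.75, lower: 30, upper: 190}
  - row: aht_use
    kind: event_flag
    concept_id: D_AHT
    days_before: 3650
    synth: {emit_concept: D_ACE}
  - row: angina
    kind: event_flag
    concept_id: C_ANGINA
    days_before: 3650
  - row: mi_history
    kind: event_flag
    concept_id: C_MI_HISTORY
    days_before: 3650
  - row: coronary_revasc
    kind: event_flag
    concept_id: P_REVASC
    days_before: 3650
    synth: {emit_concept: P_PCI}
  - row: stroke
    kind: event_flag
    concept_id: C_STROKE
    days_before: 3650
  - row: lipid_disorder
    kind: event_flag
    concept_id: C_LIPID_DISORDER
    days_before: 3650
    synth: {emit_concept: C_HYPERCHOL}
  - row: amputation
    kind: event_flag
    concept_id: P_AMPUTATION
    days_before: 3650
  - row: neuropathy
    kind: event_flag
    concept_id: C_NEUROPATHY
    days_before: 3650
  - row: retinopathy
    kind: event_flag
    concept_id: C_RETINOPATHY
    days_before: 3650
  - row: current_smoking
    kind: event_flag
    concept_id: C_SMOKING
    days_before: 3650
  - row: uacr
    kind: measurement
    concept_id: M_UACR
    days_before: 365
    aggregate: median
    synth: {sd: 0.0}       # NED in the source column -> recording probability 0
  - row: serum_creatinine
    kind: measurement
    concept_id: M_CREATININE
    days_before: 365
    synth: {sd: 0.5, lower: 0.3, upper: 15}
  - row: total_cholesterol
    kind: measurement
    concept_id: M_TC
    days_before: 365
    synth: {sd: 55.5, lower: 20, upper: 500}
  - row: ldl
    kind: measurement
    concept_id: M_LDL
    days_before: 365
    synth: {sd: 45.99, lower: 10, upper: 400}
  - row: hdl
    kind: measurement
    concept_id: M_HDL
    days_before: 365
    synth: {sd: 15.5, lower: 5, upper: 120}
  - row: triglycerides
    kind: measurement
    concept_id: M_TG
    days_before: 365
    synth: {sd: 190.07, distribution: lognormal}
  - row: hemoglobin
    kind: measurement
    concept_id: M_HGB
    days_before: 365
    synth: {sd: 1.85, lower: 4, upper: 22}
  - row: hba1c
    kind: measurement
    concept_id: M_HBA1C
    days_before: 365
    synth: {sd: 1.65, lower: 3.5, upper: 16}
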