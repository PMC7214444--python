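# Emulation map: atorvastatin vs. pravastatin after acute coronary syndrome.
# The index event is the qualifying ACS hospitalization; its subtype
# (unstable angina / NSTEMI / STEMI) is drawn with the indication-only
# column's proportions. Lipids are median-reported with no sigma column, so
# cohort SDs here are plausible adult values chosen once.
population:
  n_persons: 9930
  indication: {concept_id: C_ACS, prevalence: 0.4}

link_exclude: []

characteristics:
  - kind: demographic_category
    field: gender
    categories: {G_MALE: male, G_FEMALE: female, G_UNKNOWN: sex_unknown}
  - kind: demographic_category
    field: race
    categories: {R_WHITE: race_white, R_OTHER: race_other}
  - row: age
    kind: age
    synth: {sd: 11.25}
  - row: diabetes
    kind: event_flag
    concept_id: C_DM
    days_before: 3650
    synth: {emit_concept: C_T2DM}
  - row: hypertension
    kind: event_flag
    concept_id: C_HTN
    days_before: 3650
    synth: {emit_concept: C_ESS_HTN}
  - row: current_smoker
    kind: event_flag
    concept_id: C_SMOKING
    days_before: 3650
  - row: prior_mi
    kind: event_flag
    concept_id: C_MI_HISTORY
    days_before: 3650
  - row: pci_before_index
    kind: event_flag
    concept_id: P_PCI
    days_before: 3650
    days_after: 0
    synth: {placement: pre_index, span_days: 1825}
  - row: pci_after_index
    kind: event_flag
    concept_id: P_PCI
    days_before: 0
    days_after: 3650
    synth: {placement: post_index, span_days: 180}
  - row: coronary_bypass
    kind: event_flag
    concept_id: P_CABG
    days_before: 3650
  - row: pad
    kind: event_flag
    concept_id: C_PAD
    days_before: 3650
  - row: prior_statin
    kind: event_flag
    concept_id: D_STATIN
    days_before: 3650
    synth: {emit_concept: D_PRAVA}
  - kind: index_subtypes
    rows:
      index_unstable_angina: C_UA
      index_nstemi: C_NSTEMI
      index_stemi: C_STEMI
  - row: total_cholesterol
    kind: measurement
    concept_id: M_TC
    days_before: 365
    aggregate: median
    synth: {sd: 40.0, lower: 40, upper: 350, recording_probability: 0.95}
  - row: ldl
    kind: measurement
    concept_id: M_LDL
    days_before: 365
    aggregate: median
    synth: {sd: 35.0, lower: 5, upper: 300, recording_probability: 0.95}
  - row: hdl
    kind: measurement
    concept_id: M_HDL
    days_before: 365
    aggregate: median
    synth: {sd: 13.0, lower: 10, upper: 120, recording_probability: 0.95}
  - row: triglycerides
    kind: measurement
    concept_id: M_TG
    days_before: 365
    aggregate: median
    synth: {sd: 55.0, lower: 20, upper: 600, recording_probability: 0.95}
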