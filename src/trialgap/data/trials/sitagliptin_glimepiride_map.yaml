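# Emulation map: sitagliptin vs. glimepiride (elderly type 2 diabetes).
# Marginal values (percents, means, prevalences) are read from the trial
# transcription's indication-only column at build time; this file supplies
# concept assignments, windows, and the scale parameters the published
# table does not print (SDs default to the table's sigma column; weight has
# no sigma, so a plausible adult SD is chosen here).
population:
  n_persons: 11884           # indication-only cohort n / indication prevalence
  indication: {concept_id: C_T2DM, prevalence: 0.5}

# rows whose synthetic recovery is not expected within sampling bounds:
# cohort min/max are extreme-value statistics the generator's truncation
# bounds do not emulate (the published figure likewise drops them as
# implausible).
link_exclude: [hba1c_min, hba1c_max]

# rows dropped from the paired-delta figure (implausible extreme values)
figure_exclude: [hba1c_min, hba1c_max]

characteristics:
  - kind: demographic_category
    field: gender
    categories: {G_MALE: male, G_FEMALE: female, G_UNKNOWN: sex_unknown}
  - kind: demographic_category
    field: race
    categories:
      R_WHITE: race_white
      R_MULTIRACIAL: race_multiracial
      R_NATIVE_AM: race_native_american
      R_ASIAN: race_asian
      R_BLACK: race_black
      R_PACIFIC: race_pacific_islander
      R_UNKNOWN: race_unknown
  - row: age
    kind: age
    synth: {sd: 4.85}
  - row: body_weight
    kind: measurement
    concept_id: M_WEIGHT
    days_before: 365
    synth: {sd: 16.0, lower: 30, upper: 220}   # no sigma printed for weight
  - row: bmi
    kind: measurement
    concept_id: M_BMI
    days_before: 365
    synth: {sd: 4.54, lower: 14, upper: 60}
  - row: dm_duration_years
    kind: time_since_first_event
    concept_id: C_DM
    include_descendants: false     # first generic diabetes record, not the index code
    synth: {distribution: exponential}
  - row: hba1c_mean
    kind: measurement
    concept_id: M_HBA1C
    days_before: 365
    category:
      bins:
        - {name: hba1c_lt8, op: lt, high: 8.0}
        - {name: hba1c_ge8, op: ge, low: 8.0}
      unknown_name: hba1c_unknown
    extra_aggregates: {min: hba1c_min, max: hba1c_max}
    synth:
      # cohort SD back-solved so that P(HbA1c >= 8 | recorded) matches the
      # printed dichotomized row under normality
      sd_from_fraction: {ge_row: hba1c_ge8, unknown_row: hba1c_unknown, bound: 8.0}
      lower: 3.5
      upper: 16.0
  - row: fpg
    kind: measurement
    concept_id: M_FPG
    days_before: 365
    synth: {sd: 33.21, lower: 40, upper: 500}
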