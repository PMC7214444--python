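# Emulation map: benazepril-amlodipine vs. benazepril-HCTZ in systolic
# hypertension. The age distribution is solved from the two printed
# exceedance rows (>=65, >=70). Waist circumference and eGFR are NED in the
# source column (eGFR flagged as biased there), so their recording
# probabilities are zero. The previous-antihypertensive-treatment ordinal
# rows are a documented guess: drug classes are emitted independently (beta
# blockers at their printed prevalence, the other four classes at 0.0346
# each so that roughly three quarters of patients carry no class, as the
# source column shows) and the counts emerge from the class events; these
# rows and the race Unknown remainder are excluded from marginal-recovery
# checks (the printed race column sums to 96.6%, and the shortfall is
# assigned to Unknown).
population:
  n_persons: 61423
  indication: {concept_id: C_ESS_HTN, prevalence: 0.6}
  extra_events:
    - {concept_id: D_ACE, prevalence: 0.0346, span_days: 365}
    - {concept_id: D_ARB, prevalence: 0.0346, span_days: 365}
    - {concept_id: D_CCB, prevalence: 0.0346, span_days: 365}
    - {concept_id: D_DIURETIC, prevalence: 0.0346, span_days: 365}

link_exclude: [aht_0, aht_1, aht_2, aht_ge3, race_unknown]

characteristics:
  - kind: age_flags
    rows: {age_ge65: 65, age_ge70: 70}
  - kind: demographic_category
    field: gender
    categories: {G_FEMALE: female, G_MALE: male, G_UNKNOWN: sex_unknown}
  - kind: demographic_category
    field: race
    remainder: race_unknown
    categories:
      R_WHITE: race_white
      R_BLACK: race_black
      R_HISPANIC: race_hispanic
      R_OTHER: race_other
      R_UNKNOWN: race_unknown
  - row: weight
    kind: measurement
    concept_id: M_WEIGHT
    days_before: 365
    synth: {sd: 18.95, lower: 25, upper: 250}
  - row: waist
    kind: measurement
    concept_id: M_WAIST
    days_before: 365
    synth: {sd: 0.0}          # NED in the source column
  - row: bmi
    kind: measurement
    concept_id: M_BMI
    days_before: 365
    synth: {sd: 6.2, lower: 12, upper: 60}
  - row: sbp
    kind: measurement
    concept_id: M_SBP
    days_before: 365
    synth: {sd: 18.25, lower: 70, upper: 250}
  - row: dbp
    kind: measurement
    concept_id: M_DBP
    days_before: 365
    synth: {sd: 10.75, lower: 40, upper: 140}
  - row: pulse
    kind: measurement
    concept_id: M_PULSE
    days_before: 365
    synth: {sd: 11.0, lower: 30, upper: 180}
  - row: egfr
    kind: measurement
    concept_id: M_EGFR
    days_before: 365
    synth: {sd: 0.0}          # NED (biased reporting) in the source column
  - row: creatinine
    kind: measurement
    concept_id: M_CREATININE
    days_before: 365
    synth: {sd: 0.3, lower: 0.2, upper: 15}
  - row: glucose
    kind: measurement
    concept_id: M_GLUCOSE
    days_before: 365
    synth: {sd: 46.6, distribution: lognormal}
  - row: potassium
    kind: measurement
    concept_id: M_POTASSIUM
    days_before: 365
    synth: {sd: 0.4, lower: 2, upper: 9}
  - row: total_cholesterol
    kind: measurement
    concept_id: M_TC
    days_before: 365
    synth: {sd: 39.9, lower: 70, upper: 400}
  - row: hdl
    kind: measurement
    concept_id: M_HDL
    days_before: 365
    synth: {sd: 14.1, lower: 10, upper: 150}
  - kind: event_count_category
    concept_ids: [D_ACE, D_ARB, D_BB, D_CCB, D_DIURETIC]
    days_before: 365
    bins:
      - {name: aht_0, min_count: 0, max_count: 0}
      - {name: aht_1, min_count: 1, max_count: 1}
      - {name: aht_2, min_count: 2, max_count: 2}
      - {name: aht_ge3, min_count: 3}
    synth: {skip: true}       # class events carry the signal; counts emerge
  - row: lipid_lowering
    kind: event_flag
    concept_id: D_LIPID_LOWERING
    days_before: 3650
    synth: {emit_concept: D_STATIN}
  - row: beta_blockers
    kind: event_flag
    concept_id: D_BB
    days_before: 365
    synth: {span_days: 365}
  - row: antiplatelet
    kind: event_flag
    concept_id: D_ANTIPLATELET
    days_before: 3650
    synth: {emit_concept: D_ASPIRIN}
  - row: prev_mi
    kind: event_flag
    concept_id: C_MI_HISTORY
    days_before: 3650
  - row: prev_stroke
    kind: event_flag
    concept_id: C_STROKE
    days_before: 3650
  - row: prev_ua_hosp
    kind: event_flag
    concept_id: C_UA_HOSP
    days_before: 3650
  - row: diabetes
    kind: event_flag
    concept_id: C_DM
    days_before: 3650
    synth: {emit_concept: C_T2DM}
  - row: renal_disease
    kind: event_flag
    concept_id: C_RENAL_DISEASE
    days_before: 3650
  - row: egfr_lt60
    kind: event_flag
    concept_id: C_EGFR_LT60
    days_before: 3650
  - row: prev_coronary_revasc
    kind: event_flag
    concept_id: P_REVASC
    days_before: 3650
    synth: {skip: true}       # union of the CABG and PCI events below
  - row: cabg
    kind: event_flag
    concept_id: P_CABG
    days_before: 3650
  - row: pci
    kind: event_flag
    concept_id: P_PCI
    days_before: 3650
  - row: lvh
    kind: event_flag
    concept_id: C_LVH
    days_before: 3650
  - row: current_smoking
    kind: event_flag
    concept_id: C_SMOKING
    days_before: 3650
  - row: dyslipidemia
    kind: event_flag
    concept_id: C_LIPID_DISORDER
    days_before: 3650
    synth: {emit_concept: C_HYPERCHOL}
  - row: afib
    kind: event_flag
    concept_id: C_AFIB
    days_before: 3650
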