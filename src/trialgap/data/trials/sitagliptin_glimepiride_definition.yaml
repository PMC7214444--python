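# Elderly type 2 diabetes add-on trial: representative operationalizable
# criteria subset (age floor, glycemic window at screening, no type 1
# diabetes). Soft criteria are marked unoperationalizable and skipped.
name: sitagliptin_glimepiride
indication:
  name: type_2_diabetes
  kind: has_event
  concept_set:
    included: [{concept_id: C_T2DM, include_descendants: true}]
eligibility:
  - name: age_at_least_65
    kind: age_range
    min_age: 65
  - name: hba1c_6_5_to_9
    kind: measurement_threshold
    concept_set:
      included: [{concept_id: M_HBA1C, include_descendants: false}]
    days_before: 365
    comparator: between
    low: 6.5
    high: 9.0
  - name: no_type_1_diabetes
    kind: absent_event
    concept_set:
      included: [{concept_id: C_T1DM, include_descendants: true}]
    days_before: 36500
  - name: able_to_perform_self_monitoring
    kind: unoperationalizable
    description: judgment call by the treating clinician; no coded representation
mode: indication_plus_criteria
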