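# Diabetic nephropathy trial: ages 31-70, screening serum creatinine
# 1.3-3.0 mg/dL, no type 1 diabetes.
name: renaal
indication:
  name: diabetic_nephropathy
  kind: has_event
  concept_set:
    included: [{concept_id: C_DM_NEPHRO, include_descendants: true}]
eligibility:
  - name: age_31_to_70
    kind: age_range
    min_age: 31
    max_age: 70
  - name: serum_creatinine_1_3_to_3_0
    kind: measurement_threshold
    concept_set:
      included: [{concept_id: M_CREATININE, include_descendants: false}]
    days_before: 365
    comparator: between
    low: 1.3
    high: 3.0
  - name: no_type_1_diabetes
    kind: absent_event
    concept_set:
      included: [{concept_id: C_T1DM, include_descendants: true}]
    days_before: 36500
mode: indication_plus_criteria
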