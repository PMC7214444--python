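# Systolic hypertension outcome trial: age 55 or older with at least one
# qualifying cardiovascular or renal risk marker.
name: accomplish
indication:
  name: hypertension
  kind: has_event
  concept_set:
    included: [{concept_id: C_HTN, include_descendants: true}]
eligibility:
  - name: age_at_least_55
    kind: age_range
    min_age: 55
  - name: high_risk_history
    kind: has_event
    concept_set:
      included:
        - {concept_id: C_DM, include_descendants: true}
        - {concept_id: C_STROKE, include_descendants: true}
        - {concept_id: C_MI_HISTORY, include_descendants: true}
        - {concept_id: C_RENAL_DISEASE, include_descendants: true}
        - {concept_id: C_LVH, include_descendants: true}
    days_before: 3650
mode: indication_plus_criteria
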