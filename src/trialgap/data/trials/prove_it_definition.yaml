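# Post-ACS statin trial: index at the qualifying acute coronary syndrome
# event; adults with screening total cholesterol at or below 240 mg/dL.
name: prove_it
indication:
  name: acute_coronary_syndrome
  kind: has_event
  concept_set:
    included: [{concept_id: C_ACS, include_descendants: true}]
eligibility:
  - name: age_at_least_18
    kind: age_range
    min_age: 18
  - name: total_cholesterol_at_most_240
    kind: measurement_threshold
    concept_set:
      included: [{concept_id: M_TC, include_descendants: false}]
    days_before: 365
    comparator: le
    high: 240.0
mode: indication_plus_criteria
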