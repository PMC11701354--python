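name: default
version: "1"
indicators:
  - name: prior_back_surgery
    role: including
    field: prior_back_surgery
    comparator: eq
    threshold: true
  - name: pain_location_leg_or_mixed
    role: including
    field: pain_location
    comparator: in
    threshold: [leg, mixed]
  - name: neuropathic_pain_dn4
    role: including
    field: dn4_score
    comparator: gt
    threshold: 3
  - name: pain_duration_3_months
    role: including
    field: pain_duration_months
    comparator: ge
    threshold: 3
  - name: leg_pain_ge_back_pain
    role: including
    field: nprs_leg
    comparator: ge
    threshold: {field: nprs_back}
  - name: nprs_leg_ge_5
    role: including
    field: nprs_leg
    comparator: ge
    threshold: 5
  - name: no_absolute_contraindication
    role: excluding
    field: absolute_contraindication
    comparator: eq
    threshold: false
  - name: no_widespread_pain
    role: excluding
    field: widespread_pain
    comparator: eq
    threshold: false
  - name: no_substance_abuse
    role: excluding
    field: substance_abuse
    comparator: eq
    threshold: false
  - name: no_response_conservative_treatment
    role: excluding
    field: responded_conservative
    comparator: eq
    threshold: false
  - name: no_prior_scs
    role: excluding
    field: prior_scs
    comparator: eq
    threshold: false
  - name: no_anatomic_abnormality
    role: excluding
    field: anatomic_abnormality
    comparator: eq
    threshold: false
  - name: adult_age
    role: excluding
    field: age_years
    comparator: gt
    threshold: 18
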