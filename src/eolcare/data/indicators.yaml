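# Default end-of-life quality-of-care indicator set.  Each indicator is
# count-of-qualifying-events >= threshold within a days-before-death
# window (day 0 = day of death).  These defaults mirror indicator
# constructs in the end-of-life quality literature; thresholds and
# windows are placeholders to be refined with expert input (for example
# by deriving cohort-specific percentile cut-offs with derive_threshold).
- name: ed_visit_last_30d
  source: ed_visits
  window_days: 30
  threshold: 1
  direction: aggressive
- name: hospital_admission_last_30d
  source: hospital_admissions
  window_days: 30
  threshold: 1
  direction: aggressive
- name: gt14_hospital_days_last_30d
  source: hospital_days
  window_days: 30
  threshold: 15
  direction: aggressive
- name: chemotherapy_last_14d
  source: service_claims
  category: therapeutic_procedure
  items: [CHEMO01]
  window_days: 14
  threshold: 1
  direction: aggressive
- name: opioid_dispensing_last_30d
  source: dispensings
  atc_prefixes: [N02A]
  window_days: 30
  threshold: 1
  direction: palliative
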