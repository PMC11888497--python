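language: en
header: |
  You are a clinical geneticist with expert knowledge of rare diseases.
  Below is the description of a patient affected by a genetic disease.
  Provide a differential diagnosis as an ordered list of candidate
  diagnoses, the most likely diagnosis first.
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "Return the differential diagnosis in English."
sex_nouns:
  MALE: male
  FEMALE: female
  OTHER: person
  UNKNOWN: individual
sentence_with_age: "The patient was a {age} {sex_noun}."
sentence_no_age: "The patient was a {sex_noun}."
age_years: "{n}-year-old"
age_months: "{n}-month-old"
age_days: "{n}-day-old"
dur_years: "{n} years"
dur_months: "{n} months"
dur_days: "{n} days"
disease_onset: "Onset of the disease: {onset}."
feature_onset: "{label} (onset: {onset})"
observed_features: "The patient presented with the following findings: {features}."
excluded_features: "The following findings were explicitly excluded: {features}."
list_separator: ", "
final_conjunction: " and "
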