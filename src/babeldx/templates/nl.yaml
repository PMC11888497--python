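language: nl
header: |
  U bent een klinisch geneticus met grondige kennis van zeldzame
  ziekten. Hieronder staat de beschrijving van een patiënt met een
  genetische aandoening. Geef een differentiaaldiagnose als een
  geordende lijst van kandidaat-diagnoses, de meest waarschijnlijke
  diagnose eerst.
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "Geef de differentiaaldiagnose in het Engels."
sex_nouns:
  MALE: mannelijk
  FEMALE: vrouwelijk
  OTHER: non-binair
  UNKNOWN: van onbekend geslacht
sentence_with_age: "De patiënt was {sex_noun} en {age} oud."
sentence_no_age: "De patiënt was {sex_noun}."
age_years: "{n} jaar"
age_months: "{n} maanden"
age_days: "{n} dagen"
dur_years: "{n} jaar"
dur_months: "{n} maanden"
dur_days: "{n} dagen"
disease_onset: "Begin van de ziekte: {onset}."
feature_onset: "{label} (begin: {onset})"
observed_features: "De volgende bevindingen werden waargenomen: {features}."
excluded_features: "De volgende bevindingen werden expliciet uitgesloten: {features}."
list_separator: ", "
final_conjunction: " en "
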