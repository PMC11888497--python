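language: de
header: |
  Sie sind klinischer Genetiker mit fundierter Kenntnis seltener
  Erkrankungen. Nachfolgend finden Sie die Beschreibung eines Patienten
  mit einer genetischen Erkrankung. Geben Sie eine Differentialdiagnose
  als geordnete Liste von Verdachtsdiagnosen an, die wahrscheinlichste
  Diagnose zuerst.
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "Geben Sie die Differentialdiagnose auf Englisch zurück."
sex_nouns:
  MALE: männlich
  FEMALE: weiblich
  OTHER: divers
  UNKNOWN: unbekannten Geschlechts
sentence_with_age: "Die betroffene Person war {sex_noun} und {age} alt."
sentence_no_age: "Die betroffene Person war {sex_noun}."
age_years: "{n} Jahre"
age_months: "{n} Monate"
age_days: "{n} Tage"
dur_years: "{n} Jahren"
dur_months: "{n} Monaten"
dur_days: "{n} Tagen"
disease_onset: "Krankheitsbeginn: {onset}."
feature_onset: "{label} (Beginn: {onset})"
observed_features: "Es wurden die folgenden Befunde beobachtet: {features}."
excluded_features: "Die folgenden Befunde wurden ausdrücklich ausgeschlossen: {features}."
list_separator: ", "
final_conjunction: " und "
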