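language: it
header: |
  Lei è un genetista clinico esperto di malattie rare. Di seguito è
  riportata la descrizione di un paziente affetto da una malattia
  genetica. Fornisca una diagnosi differenziale come elenco ordinato di
  diagnosi candidate, prima la diagnosi più probabile.
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "Restituisca la diagnosi differenziale in inglese."
sex_nouns:
  MALE: un maschio
  FEMALE: una femmina
  OTHER: una persona non binaria
  UNKNOWN: una persona di sesso sconosciuto
sentence_with_age: "Il paziente era {sex_noun} e aveva {age}."
sentence_no_age: "Il paziente era {sex_noun}."
age_years: "{n} anni"
age_months: "{n} mesi"
age_days: "{n} giorni"
dur_years: "{n} anni"
dur_months: "{n} mesi"
dur_days: "{n} giorni"
disease_onset: "Esordio della malattia: {onset}."
feature_onset: "{label} (esordio: {onset})"
observed_features: "Il paziente presentava i seguenti segni clinici: {features}."
excluded_features: "I seguenti segni sono stati esplicitamente esclusi: {features}."
list_separator: ", "
final_conjunction: " e "
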