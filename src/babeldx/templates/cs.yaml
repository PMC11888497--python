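language: cs
header: |
  Jste klinický genetik se znalostí vzácných onemocnění. Níže je uveden
  popis pacienta s genetickým onemocněním. Uveďte diferenciální
  diagnózu jako seřazený seznam kandidátních diagnóz, nejpravděpodobnější
  diagnózu jako první.
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "Diferenciální diagnózu uveďte v angličtině."
sex_nouns:
  MALE: muž
  FEMALE: žena
  OTHER: osoba jiného pohlaví
  UNKNOWN: osoba neznámého pohlaví
sentence_with_age: "Pacientem byl(a) {sex_noun} ve věku {age}."
sentence_no_age: "Pacientem byl(a) {sex_noun}."
age_years: "{n} let"
age_months: "{n} měsíců"
age_days: "{n} dnů"
dur_years: "{n} let"
dur_months: "{n} měsíců"
dur_days: "{n} dnů"
disease_onset: "Začátek onemocnění: {onset}."
feature_onset: "{label} (začátek: {onset})"
observed_features: "Byly pozorovány následující nálezy: {features}."
excluded_features: "Následující nálezy byly výslovně vyloučeny: {features}."
list_separator: ", "
final_conjunction: " a "
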