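language: es
header: |
  Usted es un genetista clínico experto en enfermedades raras. A
  continuación se describe un paciente afectado por una enfermedad
  genética. Proporcione un diagnóstico diferencial como una lista
  ordenada de diagnósticos candidatos, primero el diagnóstico más
  probable.
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "Devuelva el diagnóstico diferencial en inglés."
sex_nouns:
  MALE: un varón
  FEMALE: una mujer
  OTHER: una persona no binaria
  UNKNOWN: una persona de sexo desconocido
sentence_with_age: "El paciente era {sex_noun} y tenía {age}."
sentence_no_age: "El paciente era {sex_noun}."
age_years: "{n} años"
age_months: "{n} meses"
age_days: "{n} días"
dur_years: "{n} años"
dur_months: "{n} meses"
dur_days: "{n} días"
disease_onset: "Inicio de la enfermedad: {onset}."
feature_onset: "{label} (inicio: {onset})"
observed_features: "El paciente presentaba los siguientes hallazgos: {features}."
excluded_features: "Se descartaron explícitamente los siguientes hallazgos: {features}."
list_separator: ", "
final_conjunction: " y "
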