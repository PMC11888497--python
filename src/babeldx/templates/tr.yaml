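language: tr
header: |
  Nadir hastalıklar konusunda uzman bir klinik genetikçisiniz. Aşağıda
  genetik bir hastalığı olan bir hastanın tanımı yer almaktadır.
  Ayırıcı tanıyı, en olası tanı ilk sırada olacak şekilde sıralı bir
  aday tanı listesi olarak veriniz.
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "Ayırıcı tanıyı İngilizce olarak veriniz."
sex_nouns:
  MALE: erkek
  FEMALE: kadın
  OTHER: birey
  UNKNOWN: cinsiyeti bilinmeyen birey
sentence_with_age: "Hasta {age} bir {sex_noun} idi."
sentence_no_age: "Hasta bir {sex_noun} idi."
age_years: "{n} yaşında"
age_months: "{n} aylık"
age_days: "{n} günlük"
dur_years: "{n} yıl"
dur_months: "{n} ay"
dur_days: "{n} gün"
disease_onset: "Hastalığın başlangıcı: {onset}."
feature_onset: "{label} (başlangıç: {onset})"
observed_features: "Şu bulgular gözlendi: {features}."
excluded_features: "Şu bulgular açıkça dışlandı: {features}."
list_separator: ", "
final_conjunction: " ve "
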