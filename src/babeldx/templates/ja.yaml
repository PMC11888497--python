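language: ja
header: |
  あなたは希少疾患に精通した臨床遺伝専門医です。以下は遺伝性疾患を持つ
  患者の症例記述です。鑑別診断として、可能性の高い順に並べた候補診断の
  リストを提示してください。
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "鑑別診断は英語で回答してください。"
sex_nouns:
  MALE: 男性
  FEMALE: 女性
  OTHER: その他の性別の患者
  UNKNOWN: 性別不明の患者
sentence_with_age: "患者は{age}の{sex_noun}であった。"
sentence_no_age: "患者は{sex_noun}であった。"
age_years: "{n}歳"
age_months: "{n}か月"
age_days: "生後{n}日"
dur_years: "{n}歳"
dur_months: "{n}か月"
dur_days: "生後{n}日"
disease_onset: "発症時期:{onset}。"
feature_onset: "{label}({onset}に発症)"
observed_features: "次の所見が認められた:{features}。"
excluded_features: "次の所見は明確に除外された:{features}。"
list_separator: "、"
final_conjunction: "および"
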