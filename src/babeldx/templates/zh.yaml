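language: zh
header: |
  您是一位熟悉罕见病的临床遗传学专家。下面是一位遗传病患者的病例描述。
  请给出鉴别诊断:按可能性从高到低排序的候选诊断列表。
example_output: |
  Example output:
  1. Name of the most likely disease
  2. Name of the second most likely disease
  3. Name of the third most likely disease
answer_directive: "请用英文返回鉴别诊断。"
sex_nouns:
  MALE: 男性
  FEMALE: 女性
  OTHER: 其他性别患者
  UNKNOWN: 性别不明的患者
sentence_with_age: "患者为{age}的{sex_noun}。"
sentence_no_age: "患者为{sex_noun}。"
age_years: "{n}岁"
age_months: "{n}个月大"
age_days: "{n}天大"
dur_years: "{n}岁"
dur_months: "{n}个月"
dur_days: "{n}天"
disease_onset: "起病时间:{onset}。"
feature_onset: "{label}({onset}起病)"
observed_features: "患者表现出以下症状:{features}。"
excluded_features: "明确排除了以下症状:{features}。"
list_separator: "、"
final_conjunction: "和"
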