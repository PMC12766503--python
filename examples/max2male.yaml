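# Minimal quota example: sample of 6, no blocks, at most 2 male enrollees.
dedup_mode: review

schema:
  - {name: first_name, role: identifier, normalizer: text}
  - {name: last_name,  role: identifier, normalizer: text}
  - {name: sex,        role: demographic, normalizer: text}

criteria:
  window_days: 183
  rules:
    - {label: name, fields: [first_name, last_name]}

quota:
  total_n: 6
  rules:
    - {label: male-max, when: {sex: male}, bound: max, amount: 2, kind: count}
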