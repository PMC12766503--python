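# Smoking-cessation DCT screening setup: duplicate criteria of
# first+last name OR email OR phone within ~6 months, plus enrollment
# minimums over cigarettes-per-day bins for a target sample of 143.
timezone: America/New_York
seed: 20240101
dedup_mode: review

schema:
  - {name: first_name, role: identifier, normalizer: text}
  - {name: last_name,  role: identifier, normalizer: text}
  - {name: email,      role: identifier, normalizer: email}
  - {name: phone,      role: identifier, normalizer: phone}
  - {name: cpd_bin,    role: demographic, normalizer: exact}

criteria:
  window_days: 183
  rules:
    - {label: name,  fields: [first_name, last_name]}
    - {label: email, fields: [email]}
    - {label: phone, fields: [phone]}

quota:
  total_n: 143
  check_time: screening
  rules:
    - {label: bin_1-5,   when: {cpd_bin: "1-5"},   bound: min, amount: 23, kind: count}
    - {label: bin_6-10,  when: {cpd_bin: "6-10"},  bound: min, amount: 23, kind: count}
    - {label: bin_11-15, when: {cpd_bin: "11-15"}, bound: min, amount: 23, kind: count}
    - {label: bin_16+,   when: {cpd_bin: "16+"},   bound: min, amount: 23, kind: count}
    - {label: bin_quit,  when: {cpd_bin: "quit"},  bound: min, amount: 36, kind: count}

simulate:
  n_identities: 400
  fraud_fraction: 0.10
  mistake_fraction: 0.08
  fraud_resubmissions: [2, 15]
  category_mix:
    cpd_bin: {"1-5": 0.2, "6-10": 0.2, "11-15": 0.2, "16+": 0.2, "quit": 0.2}
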