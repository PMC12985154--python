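# Synthetic sex/age-stratified standard weekly wages (USD/week) for testing
# and examples. Real analyses substitute national labour-survey wages in
# this schema; bands must partition ages 19-69.
label: toy standard weekly wages (synthetic)
values:
  F: {"19-39": 430, "40-54": 520, "55-69": 450}
  M: {"19-39": 480, "40-54": 580, "55-69": 500}
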