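# Synthetic sex/age-stratified mean payer benefit per additional outpatient
# visit (USD). Real analyses substitute claims-derived benefits in this
# schema; bands must partition ages 19-69.
label: toy payer benefits per visit (synthetic)
values:
  F: {"19-39": 14, "40-54": 16, "55-69": 17}
  M: {"19-39": 14, "40-54": 16, "55-69": 17}
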