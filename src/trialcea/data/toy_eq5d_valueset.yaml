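# Synthetic five-level tariff for testing and examples only.
# This is NOT a national EQ-5D-5L value set; real tariffs must be supplied
# by the user in this same schema.
label: toy-eq5d-5l (synthetic)
full_health_value: 1.0
decrements:
  MO: {2: 0.05, 3: 0.10, 4: 0.17, 5: 0.25}
  SC: {2: 0.04, 3: 0.08, 4: 0.14, 5: 0.20}
  UA: {2: 0.03, 3: 0.07, 4: 0.12, 5: 0.18}
  PD: {2: 0.05, 3: 0.11, 4: 0.18, 5: 0.24}
  AD: {2: 0.04, 3: 0.09, 4: 0.15, 5: 0.21}
n_level_constant: 0.0
n_level_threshold: 5
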