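# Synthetic SF-6D style scoring equation for testing and examples only.
# This is NOT the published SF-6D algorithm; real coefficients must be
# supplied by the user in this same schema.
label: toy-sf6d (synthetic)
intercept: 1.0
decrements:
  PF:   {2: 0.03, 3: 0.06}
  RL:   {2: 0.03, 3: 0.05, 4: 0.06}
  SF:   {2: 0.04, 3: 0.06, 4: 0.08, 5: 0.10}
  PAIN: {2: 0.02, 3: 0.05, 4: 0.09, 5: 0.14}
  MH:   {2: 0.03, 3: 0.06, 4: 0.10, 5: 0.13}
  VIT:  {2: 0.02, 3: 0.04, 4: 0.07, 5: 0.09}
most_severe_constant: 0.05
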