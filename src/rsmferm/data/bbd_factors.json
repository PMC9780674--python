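[
  {"name": "beef_broth", "unit": "%", "center": 30, "step": 10},
  {"name": "peptone", "unit": "%", "center": 0.3, "step": 0.2},
  {"name": "glucose", "unit": "%", "center": 2, "step": 1}
]
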