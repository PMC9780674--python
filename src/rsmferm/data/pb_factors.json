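[
  {"name": "beef_broth", "unit": "%", "low": 30, "high": 50},
  {"name": "peptone", "unit": "%", "low": 0.30, "high": 0.70},
  {"name": "yeast_extract", "unit": "%", "low": 0.10, "high": 0.25},
  {"name": "glucose", "unit": "%", "low": 1, "high": 4},
  {"name": "KH2PO4", "unit": "%", "low": 0.10, "high": 0.40},
  {"name": "MgSO4", "unit": "%", "low": 0.01, "high": 0.04}
]
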