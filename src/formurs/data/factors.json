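[
  {"name": "CC", "low": 0.1, "high": 0.3, "units": "% w/v"},
  {"name": "CT", "low": 3.0, "high": 7.0, "units": ""},
  {"name": "CP", "low": 0.25, "high": 0.5, "units": ""}
]
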