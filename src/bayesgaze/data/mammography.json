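{
  "context_id": "mammography",
  "labels": {"event_a": "breast cancer", "event_b": "positive mammogram"},
  "branches": [0.01, 0.80, 0.096],
  "population_n": 10000
}
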