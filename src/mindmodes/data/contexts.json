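[
  {"name": "bedtime", "labels": ["warm", "soft"]},
  {"name": "hunting", "labels": ["hunt", "smell"]},
  {"name": "hunting_leaky", "labels": ["hunt", "smell", "rollover"]}
]
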