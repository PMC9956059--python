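{
  "exonic": 12,
  "missense": 5,
  "screen_pass": 40,
  "sites": 1500
}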