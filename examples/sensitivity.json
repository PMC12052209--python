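{
  "kind": "sensitivity",
  "mode": "shared",
  "parameter": "I1",
  "lo": 0.0,
  "hi": 2.0,
  "resolution": 150,
  "out_dir": "results/sensitivity"
}
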