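{
  "kind": "bifurcation_1d",
  "mode": "shared",
  "parameter": "Kg",
  "lo": 1.0,
  "hi": 40.0,
  "resolution": 400,
  "out_dir": "results/bifurcation_Kg"
}
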