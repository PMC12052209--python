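{
  "kind": "bifurcation_2d",
  "mode": "shared",
  "parameter": "I1",
  "lo": 0.0,
  "hi": 2.0,
  "resolution": 150,
  "y_parameter": "1/Jp2",
  "y_lo": 0.0,
  "y_hi": 1.0,
  "y_resolution": 21,
  "out_dir": "results/bifurcation_2d"
}
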