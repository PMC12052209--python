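{
  "kind": "clamped_compare",
  "mode": "shared",
  "parameter": "I1",
  "lo": 0.0,
  "hi": 2.0,
  "reps": 10,
  "t_end": 5000.0,
  "seed": 321,
  "clamp_reference": "empirical",
  "out_dir": "results/clamped_compare"
}
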