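{
  "kind": "ssa_sweep",
  "mode": "shared",
  "parameter": "Kg",
  "lo": 1.0,
  "hi": 40.0,
  "reps": 5,
  "t_end": 5000.0,
  "seed": 123,
  "out_dir": "results/ssa_sweep_Kg"
}
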