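{
  "kind": "ssa_single",
  "mode": "shared",
  "params": {"I1": 1.0},
  "t_end": 5000.0,
  "seed": 42,
  "out_dir": "results/ssa_single_bistable"
}
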