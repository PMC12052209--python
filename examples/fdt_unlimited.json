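{
  "kind": "fdt_curves",
  "mode": "unlimited",
  "parameter": "I1",
  "lo": 0.02,
  "hi": 2.0,
  "doses": null,
  "out_dir": "results/fdt_unlimited"
}
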