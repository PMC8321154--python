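{
  "design_type": "crystal",
  "phi_centers": [[0.0, 0.0], [12.0, 0.0], [-12.0, 0.0], [0.0, 12.0], [0.0, -12.0]],
  "frame": {"z0": 500.0, "zsd": 560.0}
}
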