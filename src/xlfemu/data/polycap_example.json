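{
  "design_type": "polycap",
  "hole_pitch_u": 2.0,
  "hole_pitch_v": 2.0,
  "n_views_u": 5,
  "n_views_v": 5,
  "a_in": 20.0,
  "a_out": 10.0,
  "energy": 9.0,
  "frame": {"z0": 10.0, "zsd": 60.0}
}
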