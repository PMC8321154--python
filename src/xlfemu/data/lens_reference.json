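{
  "design_type": "lens",
  "f1": 41.12954329956683,
  "f2": 8.78,
  "z0_cam": 49.48,
  "z1": 243.71,
  "z2": 8.78,
  "ml_diameter": 1000.0,
  "mla_lens_diameter": 32.0,
  "mla_pitch": 36.0,
  "sensor_pixel": 4.0,
  "n_views_u": 9,
  "n_views_v": 9
}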