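{
  "camera_distance_mm": 1900.0,
  "head_forward_cm": 3.0,
  "knee_alignment_deg": 4.0,
  "pelvic_obliquity_deg": 1.0,
  "pelvic_tilt_deg": 18.0,
  "scapula_tilt_deg": 7.0,
  "scoliosis_deg": 2.5,
  "seed": 42,
  "shoulder_tilt_deg": 3.0,
  "shoulder_width_mm": 470.0,
  "stature_mm": 1830.0
}
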