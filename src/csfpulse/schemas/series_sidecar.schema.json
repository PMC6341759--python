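{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PC-MRI series sidecar",
  "type": "object",
  "required": ["venc_cm_s", "pixel_spacing_mm", "period_s", "gating", "n_frames"],
  "properties": {
    "venc_cm_s": {"type": "number", "exclusiveMinimum": 0, "description": "velocity encoding parameter, cm/s"},
    "pixel_spacing_mm": {"type": "number", "exclusiveMinimum": 0},
    "period_s": {"type": "number", "exclusiveMinimum": 0, "description": "cardiac period, seconds"},
    "bpm": {"type": "number"},
    "gating": {"enum": ["ecg", "ppg"]},
    "n_frames": {"type": "integer", "minimum": 8},
    "frame_times": {"type": "array", "items": {"type": "number", "minimum": 0, "exclusiveMaximum": 1}},
    "seed": {"type": ["integer", "null"]}
  }
}
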