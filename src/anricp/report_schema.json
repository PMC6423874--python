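{
  "type": "object",
  "required": ["m1_mm", "m1_assigned_mm", "m3_pct"],
  "properties": {
    "m1_mm": {"type": "number"},
    "m1_assigned_mm": {"type": "number"},
    "m2_units": {"type": ["number", "null"]},
    "m3_pct": {"type": "number"},
    "correspondence_histogram": {"type": ["array", "null"], "items": {"type": "integer"}},
    "distance_histogram": {"type": ["array", "null"], "items": {"type": "integer"}},
    "correspondence_map": {"type": ["array", "null"]},
    "distance_map": {"type": ["array", "null"]}
  }
}
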