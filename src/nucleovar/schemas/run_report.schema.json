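{
  "type": "object",
  "required": [
    "fingerprint",
    "stage_counts",
    "pooled_spectrum",
    "concordance",
    "densities",
    "richness"
  ],
  "properties": {
    "fingerprint": {"type": "string"},
    "stage_counts": {
      "type": "object",
      "required": ["truth_sites", "pooled_initial_calls", "nuclei_initial_calls"],
      "properties": {
        "truth_sites": {"type": "integer"},
        "pooled_initial_calls": {"type": "integer"},
        "nuclei_initial_calls": {"type": "integer"}
      }
    },
    "pooled_spectrum": {"type": "array"},
    "nucleus_spectrum": {"type": "array"},
    "concordance": {
      "type": "object",
      "required": ["shared", "pooled_exclusive", "nuclei_exclusive", "shared_percentage"],
      "properties": {
        "shared": {"type": "integer"},
        "pooled_exclusive": {"type": "integer"},
        "nuclei_exclusive": {"type": "integer"},
        "shared_percentage": {"type": "number"}
      }
    },
    "densities": {"type": "array"},
    "richness": {"type": "object"}
  }
}
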