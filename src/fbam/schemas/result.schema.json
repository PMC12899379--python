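{
  "type": "object",
  "required": ["schema_version", "provenance", "mode", "selected", "loss", "labels", "groups", "criterion_table"],
  "properties": {
    "schema_version": {"type": "integer"},
    "mode": {"type": "string", "enum": ["joint", "bands_only", "subpops_only"]},
    "loss": {"type": "number"},
    "provenance": {
      "type": "object",
      "required": ["seed", "T", "K", "n_tapers", "config"],
      "properties": {
        "seed": {"type": "integer"},
        "T": {"type": "integer"},
        "K": {"type": "integer"},
        "M": {"type": "integer"},
        "n_tapers": {"type": "integer"},
        "sampling_rate": {"type": ["number", "null"]},
        "config": {"type": "object"}
      }
    },
    "selected": {
      "type": "object",
      "required": ["J", "L"],
      "properties": {"J": {"type": "integer"}, "L": {"type": "integer"}}
    },
    "labels": {"type": "array", "items": {"type": "integer"}},
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["group", "size", "cut_indices", "cut_frequencies", "band_means", "band_sizes"],
        "properties": {
          "group": {"type": "integer"},
          "size": {"type": "integer"},
          "cut_indices": {"type": "array", "items": {"type": "integer"}},
          "cut_frequencies": {"type": "array", "items": {"type": "number"}},
          "cut_frequencies_hz": {"type": "array", "items": {"type": "number"}},
          "band_means": {"type": "array", "items": {"type": "number"}},
          "band_sizes": {"type": "array", "items": {"type": "integer"}}
        }
      }
    },
    "criterion_table": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["J", "L", "loss"],
        "properties": {
          "J": {"type": "integer"},
          "L": {"type": "integer"},
          "loss": {"type": "number"},
          "S1": {"type": ["number", "null"]},
          "S2": {"type": ["number", "null"]},
          "scaled_sum": {"type": ["number", "null"]}
        }
      }
    }
  }
}
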