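{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "StratificationResult",
  "type": "object",
  "required": ["tier", "high_tau", "mcc", "step1", "step2", "config_fingerprint"],
  "properties": {
    "tier": {"type": "string", "enum": ["tau_ad_negative", "tau_ad_plus", "tau_ad_plusplus"]},
    "high_tau": {"type": "boolean"},
    "mcc": {
      "type": "object",
      "required": ["value", "n_voxels", "method"],
      "properties": {
        "value": {"type": "number"},
        "n_voxels": {"type": "integer"},
        "method": {"type": "string", "enum": ["mask3d", "slice2d"]}
      }
    },
    "step1": {"$ref": "#/$defs/score_set"},
    "step2": {"anyOf": [{"$ref": "#/$defs/score_set"}, {"type": "null"}]},
    "config_fingerprint": {"type": "string"}
  },
  "$defs": {
    "score_set": {
      "type": "object",
      "required": ["multiplier", "threshold_value", "scores", "max_cluster_voxels"],
      "properties": {
        "multiplier": {"type": "number"},
        "threshold_value": {"type": "number"},
        "scores": {"type": "object"},
        "max_cluster_voxels": {"type": "object"}
      }
    }
  }
}
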