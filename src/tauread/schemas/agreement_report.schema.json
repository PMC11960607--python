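{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "AgreementReport",
  "type": "object",
  "required": [
    "per_reader", "pooled", "median_ppa_pct", "median_npa_pct",
    "median_overall_pct", "fleiss", "success_ppa_npa", "success_fleiss", "level"
  ],
  "properties": {
    "per_reader": {"type": "object"},
    "pooled": {"$ref": "#/$defs/endpoints"},
    "median_ppa_pct": {"type": "number"},
    "median_npa_pct": {"type": "number"},
    "median_overall_pct": {"type": "number"},
    "fleiss": {"anyOf": [{"$ref": "#/$defs/kappa"}, {"type": "null"}]},
    "success_ppa_npa": {"type": "boolean"},
    "success_fleiss": {"type": "boolean"},
    "level": {"type": "number"}
  },
  "$defs": {
    "proportion": {
      "type": "object",
      "required": ["numerator", "denominator", "point_pct", "ci_low_pct", "ci_high_pct", "level"],
      "properties": {
        "numerator": {"type": "integer"},
        "denominator": {"type": "integer"},
        "point_pct": {"type": "number"},
        "ci_low_pct": {"type": "number"},
        "ci_high_pct": {"type": "number"},
        "level": {"type": "number"}
      }
    },
    "endpoints": {
      "type": "object",
      "required": ["ppa", "npa", "overall"],
      "properties": {
        "ppa": {"$ref": "#/$defs/proportion"},
        "npa": {"$ref": "#/$defs/proportion"},
        "overall": {"$ref": "#/$defs/proportion"}
      }
    },
    "kappa": {
      "type": "object",
      "required": ["statistic", "se", "ci_low", "ci_high", "method", "level"],
      "properties": {
        "statistic": {"type": "number"},
        "se": {"type": "number"},
        "ci_low": {"type": "number"},
        "ci_high": {"type": "number"},
        "method": {"type": "string"},
        "level": {"type": "number"}
      }
    }
  }
}
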