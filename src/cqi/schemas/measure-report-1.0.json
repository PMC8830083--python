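{
  "$comment": "Layout of a measure report JSON document (schema version 1.0). Enforced by cqi.reporting.validate_report_dict.",
  "type": "object",
  "required": ["schema_version", "indicator", "parameters", "counts",
               "repository_rows", "populations"],
  "properties": {
    "schema_version": {"type": "string", "const": "1.0"},
    "indicator": {
      "type": "object",
      "required": ["name", "version", "status", "measure_type"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"},
        "status": {"type": "string"},
        "measure_type": {"enum": ["proportion", "count"]}
      }
    },
    "parameters": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "counts": {
      "type": "object",
      "additionalProperties": {"type": "integer", "minimum": 0}
    },
    "score": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
    "score_exact": {"type": ["string", "null"]},
    "observation_total": {"type": ["number", "null"]},
    "repository_rows": {
      "type": "object",
      "additionalProperties": {"type": "integer", "minimum": 0}
    },
    "populations": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": "string"}}
    },
    "evaluation_time": {"type": "string"}
  }
}
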