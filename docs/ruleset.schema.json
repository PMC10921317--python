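{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "crcguide ruleset",
  "description": "Row-enumerated guideline decision tables. Documentation of the YAML format accepted by crcguide.ruleset.load_ruleset; the loader performs equivalent structural validation itself.",
  "type": "object",
  "required": ["sections", "manifest", "charlson", "vocabulary"],
  "properties": {
    "meta": {"type": "object"},
    "vocabulary": {
      "type": "object",
      "description": "Lesion feature code -> lesion class ('adenoma' | 'cssp').",
      "additionalProperties": {"enum": ["adenoma", "cssp"]}
    },
    "charlson": {
      "type": "object",
      "required": ["weights", "age_points"],
      "properties": {
        "weights": {
          "type": "object",
          "additionalProperties": {"type": "integer", "minimum": 0}
        },
        "age_points": {
          "type": "array",
          "description": "Bands must partition ages 0-120.",
          "items": {
            "type": "object",
            "required": ["label", "min", "max", "points"],
            "properties": {
              "label": {"type": "string"},
              "min": {"type": "integer"},
              "max": {"type": ["integer", "null"]},
              "points": {"type": "integer", "minimum": 0}
            }
          }
        }
      }
    },
    "cessation": {
      "type": "object",
      "properties": {"min_assessment_age": {"type": "integer"}}
    },
    "discriminators": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": "string"}}
    },
    "manifest": {
      "type": "object",
      "description": "Expected table count per section; checked at load.",
      "additionalProperties": {"type": "integer", "minimum": 1}
    },
    "sections": {
      "type": "object",
      "required": ["screening", "first_surveillance", "subsequent_surveillance", "cessation"],
      "additionalProperties": {
        "type": "array",
        "items": {"$ref": "#/$defs/table"}
      }
    }
  },
  "$defs": {
    "band": {
      "type": "object",
      "required": ["label", "min"],
      "properties": {
        "label": {"type": "string"},
        "min": {"type": "integer"},
        "max": {"type": ["integer", "null"]}
      }
    },
    "variable": {
      "type": "object",
      "required": ["name", "kind", "source"],
      "properties": {
        "name": {"type": "string"},
        "kind": {"enum": ["integer-range", "category", "boolean"]},
        "source": {
          "type": "string",
          "description": "Case field or derived quantity feeding the variable, e.g. family_history.first_degree_count, findings.adenoma_risk, context.prior_interval, charlson_score."
        },
        "bands": {"type": "array", "items": {"$ref": "#/$defs/band"}},
        "values": {"type": "array", "items": {"type": "string"}},
        "absent_label": {"type": "string"},
        "na_if": {
          "type": "object",
          "required": ["var", "equals"],
          "description": "This variable takes absent_label exactly when the named variable equals the given value."
        }
      }
    },
    "table": {
      "type": "object",
      "required": ["id", "rows"],
      "properties": {
        "id": {"type": "string"},
        "select": {
          "type": "object",
          "description": "Discriminator values selecting this table within its section.",
          "additionalProperties": {"type": "string"}
        },
        "vars": {"type": "array", "items": {"$ref": "#/$defs/variable"}},
        "rows": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "object",
            "required": ["id", "when", "rec"],
            "properties": {
              "id": {"type": "string", "description": "Unique row id (provenance)."},
              "when": {
                "type": "object",
                "description": "Conjunction of variable -> label (or label list, meaning in-set) clauses.",
                "additionalProperties": {
                  "oneOf": [{"type": "string"},
                            {"type": "array", "items": {"type": "string"}}]
                }
              },
              "rec": {
                "type": "object",
                "description": "Recommendation payload: modality/start_age, interval (months), or continue_surveillance."
              }
            }
          }
        }
      }
    }
  }
}
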