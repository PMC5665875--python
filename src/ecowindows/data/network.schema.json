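{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ecowindows network configuration",
  "description": "Non-homogeneous dynamic Bayesian network: nodes with ordered categorical states, within-slice and previous-slice parents, dense conditional probability tables, and per-node regime selectors mapping (slice, calendar month, regime label) to a table id. Sparse or default-row CPT dialects are not valid; every parent-state combination must appear exactly once.",
  "type": "object",
  "required": ["nodes", "tables", "selectors"],
  "properties": {
    "name": {"type": "string"},
    "nodes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "states"],
        "properties": {
          "name": {"type": "string"},
          "states": {
            "type": "array",
            "items": {"type": "string"},
            "minItems": 2,
            "uniqueItems": true
          },
          "zero_state": {"type": "string"},
          "intra_parents": {"type": "array", "items": {"type": "string"}},
          "inter_parents": {"type": "array", "items": {"type": "string"}},
          "role": {
            "enum": ["environment", "site", "population", "process", "output"]
          }
        }
      }
    },
    "tables": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["child", "parent_order", "rows"],
        "properties": {
          "child": {"type": "string"},
          "parent_order": {
            "type": "array",
            "items": {"type": "string"},
            "description": "parent names; suffix [t-1] marks previous-slice parents"
          },
          "rows": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["parents", "p"],
              "properties": {
                "parents": {"type": "array", "items": {"type": "string"}},
                "p": {
                  "type": "array",
                  "items": {"type": "number", "minimum": 0, "maximum": 1},
                  "description": "probability vector over the child states; must sum to 1 within 1e-9"
                }
              }
            }
          }
        }
      }
    },
    "selectors": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "rules": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["table"],
              "properties": {
                "table": {"type": "string"},
                "months": {
                  "type": "array",
                  "items": {"type": "integer", "minimum": 1, "maximum": 12}
                },
                "slices": {
                  "type": "array",
                  "items": {"type": "integer", "minimum": 0},
                  "minItems": 2,
                  "maxItems": 2
                },
                "regime": {"type": "string"}
              }
            }
          },
          "default": {"type": "string"}
        }
      }
    }
  }
}
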