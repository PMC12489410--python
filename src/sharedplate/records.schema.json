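{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Two-method dietary intake record set",
  "description": "Hierarchy: household -> participant -> recording day -> eating occasion -> serving. Amounts are grams (number or decimal string) or an analyst-estimate set. The training/test recording day uses day_index 0 with training=true and is dropped from analysis; analysis days use day_index 1..3, unique within a period.",
  "type": "object",
  "required": ["households"],
  "properties": {
    "households": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["household_id", "participants"],
        "properties": {
          "household_id": {"type": "string"},
          "participants": {
            "type": "array",
            "description": "Exactly one mother and at most one child per household.",
            "items": {
              "type": "object",
              "required": ["participant_id", "role", "site"],
              "properties": {
                "participant_id": {"type": "string"},
                "role": {"enum": ["mother", "child"]},
                "site": {"enum": ["rural", "semirural", "urban"]},
                "days": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["period", "day_index"],
                    "properties": {
                      "period": {"enum": ["visida1", "recall", "visida2"]},
                      "day_index": {"type": "integer", "minimum": 0, "maximum": 3},
                      "is_weekend": {"type": "boolean", "default": false},
                      "training": {"type": "boolean", "default": false},
                      "occasions": {
                        "type": "array",
                        "items": {
                          "type": "object",
                          "required": ["servings"],
                          "properties": {
                            "occasion_id": {"type": "string"},
                            "servings": {
                              "type": "array",
                              "minItems": 1,
                              "items": {"$ref": "#/$defs/serving"}
                            }
                          }
                        }
                      }
                    }
                  }
                }
              }
            }
          },
          "recipes": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["recipe_id", "ingredients"],
              "properties": {
                "recipe_id": {"type": "string"},
                "ingredients": {
                  "type": "array",
                  "minItems": 1,
                  "items": {
                    "type": "object",
                    "required": ["food_id", "grams"],
                    "properties": {
                      "food_id": {"type": "string"},
                      "grams": {"type": "number", "exclusiveMinimum": 0},
                      "cooking_method": {"type": ["string", "null"]}
                    }
                  }
                },
                "final_weight": {"type": ["number", "null"], "exclusiveMinimum": 0}
              }
            }
          }
        }
      }
    }
  },
  "$defs": {
    "amount": {
      "oneOf": [
        {"type": "number", "minimum": 0},
        {"type": "string", "pattern": "^[0-9.eE+-]+$"},
        {
          "type": "object",
          "required": ["estimates"],
          "properties": {
            "estimates": {
              "type": "array",
              "minItems": 1,
              "maxItems": 3,
              "items": {
                "type": "object",
                "required": ["analyst_id", "grams"],
                "properties": {
                  "analyst_id": {"type": "string"},
                  "grams": {"type": "number", "exclusiveMinimum": 0}
                }
              }
            },
            "resolution": {"type": ["number", "null"]}
          }
        }
      ]
    },
    "serving": {
      "type": "object",
      "required": ["serving_type", "item_ref", "served_amount", "eaters"],
      "properties": {
        "serving_type": {"enum": ["own", "shared"]},
        "item_ref": {"type": "string", "description": "food_id or recipe_id"},
        "served_amount": {"$ref": "#/$defs/amount"},
        "leftover_amount": {"$ref": "#/$defs/amount"},
        "consumption_status": {
          "enum": ["eaten_completely", "not_consumed", "partial"]
        },
        "eaters": {
          "type": "object",
          "description": "Own-plate servings list exactly the owning participant and no bystanders.",
          "properties": {
            "participant_ids": {"type": "array", "items": {"type": "string"}},
            "n_nonparticipant_adults": {"type": "integer", "minimum": 0},
            "n_nonparticipant_children": {"type": "integer", "minimum": 0}
          }
        }
      }
    }
  }
}
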