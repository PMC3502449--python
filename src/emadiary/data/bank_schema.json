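{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "emadiary-item-bank-1.0",
  "title": "emadiary item-bank document, schema version 1.0",
  "type": "object",
  "required": ["scales", "delusion_templates", "reactivity_items"],
  "properties": {
    "schema_version": {"const": "1.0"},
    "scales": {
      "type": "array",
      "minItems": 14,
      "maxItems": 14,
      "items": {
        "type": "object",
        "required": ["scale_id", "name", "set", "interview_map", "items"],
        "properties": {
          "scale_id": {"type": "string"},
          "name": {"type": "string"},
          "set": {"enum": [1, 2]},
          "interview_map": {"type": "string"},
          "composite": {"enum": ["none", "delusions_composite", "depression_composite"]},
          "items": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["item_id", "text", "role"],
              "properties": {
                "item_id": {"type": "string"},
                "text": {"type": "string"},
                "role": {"enum": ["stem", "branch"]},
                "recode": {"enum": ["none", "grandiosity1"]},
                "display_condition": {
                  "type": "object",
                  "required": ["source", "comparator", "threshold"],
                  "properties": {
                    "source": {"type": "string"},
                    "comparator": {"enum": [">=", ">", "=="]},
                    "threshold": {"type": "integer", "minimum": 1, "maximum": 7}
                  }
                }
              }
            }
          }
        }
      }
    },
    "delusion_templates": {
      "type": "array",
      "minItems": 6,
      "maxItems": 6,
      "items": {
        "type": "object",
        "required": ["template_id", "statement", "sub_items"],
        "properties": {
          "template_id": {"type": "string"},
          "statement": {"type": "string"},
          "sub_items": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "string"}}
        }
      }
    },
    "reactivity_items": {
      "type": "array",
      "minItems": 2,
      "maxItems": 2,
      "items": {"type": "string"}
    }
  }
}
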