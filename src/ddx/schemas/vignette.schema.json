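{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "ddx/vignette.schema.json",
  "title": "Coded clinical vignette (one JSON-lines record)",
  "type": "object",
  "required": ["id", "findings", "stratum", "gold"],
  "properties": {
    "id": {"type": "string", "minLength": 1},
    "demographics": {
      "type": "object",
      "properties": {
        "age": {"type": "number", "minimum": 0},
        "sex": {"enum": ["female", "male", "other"]},
        "presentation_date": {"type": "string", "format": "date"}
      }
    },
    "findings": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["symptom_id", "polarity"],
        "properties": {
          "symptom_id": {"type": "string", "minLength": 1},
          "polarity": {"enum": ["present", "absent"]}
        }
      }
    },
    "stratum": {"enum": ["high", "moderate", "low"]},
    "gold": {
      "type": "object",
      "required": ["items", "k"],
      "properties": {
        "k": {"const": 3},
        "items": {
          "type": "array",
          "minItems": 3,
          "maxItems": 3,
          "items": {
            "type": "object",
            "required": ["disease_id", "rank", "surety"],
            "properties": {
              "disease_id": {"type": "string", "minLength": 1},
              "rank": {"type": "integer", "minimum": 1, "maximum": 3},
              "surety": {"type": "integer", "minimum": 0, "maximum": 100}
            }
          }
        }
      },
      "description": "sureties must sum to exactly 100; enforced semantically"
    }
  }
}
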