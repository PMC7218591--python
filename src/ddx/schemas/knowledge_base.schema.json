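{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "ddx/knowledge_base.schema.json",
  "title": "Symptom-disease knowledge base",
  "type": "object",
  "required": ["diseases", "symptoms", "weights"],
  "properties": {
    "diseases": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "pattern": "^\\S+$"},
          "name": {"type": "string"},
          "prior": {"type": "number", "minimum": 0}
        }
      }
    },
    "symptoms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "pattern": "^\\S+$"},
          "name": {"type": "string"},
          "category": {
            "enum": [
              "presenting_complaint",
              "present_illness",
              "medical_history",
              "family_history",
              "personal_history",
              "demographic"
            ]
          }
        }
      }
    },
    "weights": {
      "type": "object",
      "description": "symptom_id -> disease_id -> association weight; absent cells default to 0",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
      }
    }
  }
}
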