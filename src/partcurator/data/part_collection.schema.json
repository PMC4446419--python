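{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Part collection document",
  "type": "object",
  "required": ["format_version", "collection", "parts"],
  "properties": {
    "format_version": {"const": 1},
    "collection": {
      "type": "object",
      "required": ["name", "host"],
      "properties": {
        "name": {"type": "string"},
        "host": {"type": "string"},
        "description": {"type": "string"}
      }
    },
    "parts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["display_id", "name", "sequence", "so_term"],
        "properties": {
          "display_id": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z0-9_]*$"},
          "name": {"type": "string"},
          "description": {"type": "string"},
          "sequence": {"type": "string", "pattern": "^[ACGTRYSWKMBDHVN]*$"},
          "so_term": {"type": "string", "pattern": "^SO:[0-9]{7}$"},
          "hosts": {"type": "array", "items": {"type": "string"}},
          "category_code": {"type": "string"}
        }
      }
    }
  }
}
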