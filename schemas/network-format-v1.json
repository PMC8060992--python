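{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "network-format-v1.json",
 "title": "metnav native network format, version 1",
 "type": "object",
 "required": ["format", "id", "metabolites", "reactions"],
 "properties": {
  "format": {"const": "network-format-v1"},
  "id": {"type": "string", "minLength": 1},
  "metabolites": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id"],
    "properties": {
     "id": {"type": "string", "minLength": 1},
     "name": {"type": "string"},
     "smiles": {"type": "string"},
     "is_ubiquitous": {"type": "boolean", "default": false}
    },
    "additionalProperties": false
   }
  },
  "reactions": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "left", "right"],
    "properties": {
     "id": {"type": "string", "minLength": 1},
     "left": {"$ref": "#/$defs/side"},
     "right": {"$ref": "#/$defs/side"},
     "direction": {
      "enum": ["LEFT_TO_RIGHT", "RIGHT_TO_LEFT", "REVERSIBLE", "UNSPECIFIED"],
      "default": "LEFT_TO_RIGHT"
     },
     "equation": {"type": "string"},
     "ec_number": {"type": "string"},
     "enzymes": {"type": "array", "items": {"type": "string"}},
     "genes": {"type": "array", "items": {"type": "string"}},
     "pathways": {"type": "array", "items": {"type": "string"}},
     "spontaneous": {"type": "boolean", "default": false}
    },
    "additionalProperties": false
   }
  }
 },
 "additionalProperties": false,
 "$defs": {
  "side": {
   "type": "array",
   "items": {
    "type": "array",
    "prefixItems": [
     {"type": "string", "minLength": 1},
     {"type": "number", "exclusiveMinimum": 0}
    ],
    "minItems": 2,
    "maxItems": 2
   }
  }
 }
}
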