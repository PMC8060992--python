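{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "neighborhood-v1.json",
 "title": "metnav neighborhood JSON output, version 1",
 "type": "object",
 "required": ["format", "network", "focal", "precursors", "successors"],
 "properties": {
  "format": {"const": "neighborhood-v1"},
  "network": {"type": "string"},
  "focal": {"type": "string"},
  "precursors": {"$ref": "#/$defs/entries"},
  "successors": {"$ref": "#/$defs/entries"}
 },
 "additionalProperties": false,
 "$defs": {
  "entries": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["neighbor_id", "name", "reactions", "connection_class"],
    "properties": {
     "neighbor_id": {"type": "string"},
     "name": {"type": "string"},
     "reactions": {"type": "array", "items": {"type": "string"}, "minItems": 1},
     "connection_class": {
      "enum": ["unidirectional", "bidirectional", "spontaneous", "multiple"]
     }
    },
    "additionalProperties": false
   }
  }
 }
}
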