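{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Feature track document",
  "type": "object",
  "additionalProperties": false,
  "required": ["accession", "length", "tracks"],
  "properties": {
    "accession": {"type": "string"},
    "length": {"type": "integer", "minimum": 1},
    "tracks": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["name", "provenance", "color_hint", "features"],
        "properties": {
          "name": {"type": "string"},
          "provenance": {"type": "string", "enum": ["UniProt", "PDB", "computed", "user"]},
          "color_hint": {"type": "string"},
          "features": {
            "type": "array",
            "items": {
              "type": "object",
              "additionalProperties": false,
              "required": ["start", "end", "type", "label", "attributes"],
              "properties": {
                "start": {"type": "integer", "minimum": 1},
                "end": {"type": "integer", "minimum": 1},
                "type": {
                  "type": "string",
                  "enum": ["exon", "variant", "pdb_coverage", "mismatch", "modification", "domain", "user"]
                },
                "label": {"type": "string"},
                "attributes": {
                  "type": "object",
                  "additionalProperties": {"type": "string"}
                }
              }
            }
          }
        }
      }
    }
  }
}
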