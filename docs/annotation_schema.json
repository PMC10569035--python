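{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Annotation document dialect consumed by tpcurate",
  "description": "A PUG-View-style annotation export: per-compound text excerpts with character-offset markup spans linked to compound identifiers (CIDs). Offsets are 0-based, length-counted, in Unicode code points. tpcurate validates documents with its own parser; this schema is the machine-readable reference for producers.",
  "type": "object",
  "required": ["Annotations"],
  "properties": {
    "Annotations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["SourceName", "SourceID", "Name", "LinkedRecords", "Data"],
        "properties": {
          "SourceName": {"type": "string", "description": "Data source, e.g. HSDB"},
          "SourceID": {"type": "string", "description": "Source-local record identifier"},
          "Name": {"type": "string", "description": "Input compound name"},
          "LinkedRecords": {
            "type": "object",
            "required": ["CID"],
            "properties": {
              "CID": {
                "type": "array",
                "items": {"type": "integer", "exclusiveMinimum": 0},
                "minItems": 1,
                "maxItems": 1,
                "description": "The input compound's CID"
              }
            }
          },
          "Data": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["Value"],
              "properties": {
                "Value": {
                  "type": "object",
                  "required": ["StringWithMarkup"],
                  "properties": {
                    "StringWithMarkup": {
                      "type": "array",
                      "items": {
                        "type": "object",
                        "required": ["String"],
                        "properties": {
                          "String": {"type": "string", "minLength": 1},
                          "Markup": {
                            "type": "array",
                            "items": {
                              "type": "object",
                              "required": ["Start", "Length"],
                              "properties": {
                                "Start": {"type": "integer", "minimum": 0},
                                "Length": {"type": "integer", "minimum": 1},
                                "Extra": {
                                  "type": "string",
                                  "pattern": "^CID-[0-9]+$",
                                  "description": "Linked compound identifier; absent when the name was recognized but not resolved"
                                },
                                "Text": {
                                  "type": "string",
                                  "description": "Optional copy of the covered text; must equal the excerpt slice when present"
                                }
                              }
                            }
                          }
                        }
                      }
                    }
                  }
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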