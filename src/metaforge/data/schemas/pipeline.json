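{
  "type_name": "pipeline",
  "schema_version": 1,
  "description": "A named sequence of processing steps; links the software it runs.",
  "required": [
    "title"
  ],
  "properties": {
    "title": {
      "kind": "text"
    },
    "software_used": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "software"
      }
    },
    "documents": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "document"
      }
    },
    "status": {
      "kind": "text",
      "enum": [
        "in progress",
        "released",
        "replaced",
        "deleted"
      ],
      "description": "lifecycle state; deletion is a status, never removal"
    }
  }
}
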