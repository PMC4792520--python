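{
  "type_name": "lab",
  "schema_version": 1,
  "description": "Submitting laboratory; recorded so data can be searched by lab.",
  "required": [
    "name"
  ],
  "identifying_fields": [
    "name"
  ],
  "properties": {
    "name": {
      "kind": "text"
    },
    "institute": {
      "kind": "text"
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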