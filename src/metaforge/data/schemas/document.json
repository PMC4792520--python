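{
  "type_name": "document",
  "schema_version": 1,
  "description": "Attached protocol or characterization document (metadata only).",
  "required": [
    "document_type"
  ],
  "properties": {
    "document_type": {
      "kind": "text",
      "enum": [
        "growth protocol",
        "extraction protocol",
        "antibody characterization",
        "analysis protocol",
        "general protocol"
      ]
    },
    "description": {
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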