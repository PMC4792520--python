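{
  "type_name": "software",
  "schema_version": 1,
  "description": "A software tool used in processing; version and download md5sum are captured because outputs depend on both.",
  "required": [
    "name",
    "version"
  ],
  "identifying_fields": [
    "name"
  ],
  "properties": {
    "name": {
      "kind": "text"
    },
    "version": {
      "kind": "text"
    },
    "source_url": {
      "kind": "text"
    },
    "md5sum": {
      "kind": "text",
      "pattern": "[0-9a-f]{32}"
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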