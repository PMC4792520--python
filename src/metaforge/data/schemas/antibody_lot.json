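{
  "type_name": "antibody_lot",
  "schema_version": 1,
  "description": "A specific production lot of an antibody; specificity varies lot to lot, so source + product + lot are all captured.",
  "required": [
    "source",
    "product_id",
    "lot_id"
  ],
  "properties": {
    "source": {
      "kind": "text"
    },
    "product_id": {
      "kind": "text"
    },
    "lot_id": {
      "kind": "text"
    },
    "targets": {
      "kind": "list",
      "items": {
        "kind": "text"
      }
    },
    "characterizations": {
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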