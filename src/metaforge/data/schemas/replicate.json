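{
  "type_name": "replicate",
  "schema_version": 1,
  "description": "One performance of the assay within an experiment, numbered (biological, technical) and linked to the library it sequenced.",
  "required": [
    "experiment",
    "biological_replicate_number",
    "technical_replicate_number"
  ],
  "properties": {
    "experiment": {
      "kind": "link",
      "link_to": "experiment"
    },
    "biological_replicate_number": {
      "kind": "integer"
    },
    "technical_replicate_number": {
      "kind": "integer"
    },
    "library": {
      "kind": "link",
      "link_to": "library"
    },
    "antibody": {
      "kind": "link",
      "link_to": "antibody_lot"
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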