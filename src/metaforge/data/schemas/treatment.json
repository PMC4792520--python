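{
  "type_name": "treatment",
  "schema_version": 1,
  "description": "Chemical or biological treatment applied to a biosample; the agent is identified by a ChEBI term.",
  "required": [
    "treatment_term",
    "treatment_term_name"
  ],
  "properties": {
    "treatment_term": {
      "kind": "text",
      "pattern": "[A-Za-z]+:[0-9A-Za-z_]+",
      "description": "ChEBI CURIE for the agent"
    },
    "treatment_term_name": {
      "kind": "text"
    },
    "duration": {
      "kind": "number"
    },
    "duration_units": {
      "kind": "text",
      "enum": [
        "minute",
        "hour",
        "day"
      ]
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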