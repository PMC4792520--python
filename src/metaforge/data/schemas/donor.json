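{
  "type_name": "donor",
  "schema_version": 1,
  "description": "Human donor or model-organism strain a biosample derives from.",
  "required": [
    "organism"
  ],
  "properties": {
    "organism": {
      "kind": "text",
      "enum": [
        "human",
        "mouse"
      ]
    },
    "age": {
      "kind": "text",
      "description": "age with units, e.g. '53 year'"
    },
    "sex": {
      "kind": "text",
      "enum": [
        "male",
        "female",
        "unknown"
      ]
    },
    "life_stage": {
      "kind": "text",
      "enum": [
        "embryonic",
        "child",
        "adult",
        "unknown"
      ]
    },
    "strain_background": {
      "kind": "text",
      "description": "strain name for model organisms"
    },
    "lab": {
      "kind": "link",
      "link_to": "lab"
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
  },
  "dependencies": {
    "organism": {
      "trigger_values": [
        "mouse"
      ],
      "required_fields": [
        "strain_background"
      ]
    }
  }
}
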