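{
  "type_name": "experiment",
  "schema_version": 1,
  "description": "One or more replicates grouped with their raw and processed files; the assay is identified by an OBI term. Control experiments carry a control_type and are modeled like experiments.",
  "required": [
    "assay_term",
    "assay_term_name"
  ],
  "properties": {
    "assay_term": {
      "kind": "text",
      "pattern": "[A-Za-z]+:[0-9A-Za-z_]+",
      "description": "OBI CURIE"
    },
    "assay_term_name": {
      "kind": "text"
    },
    "target": {
      "kind": "text",
      "description": "ChIP target, e.g. CTCF"
    },
    "control_type": {
      "kind": "text",
      "description": "present iff this experiment is itself a control"
    },
    "replicates": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "replicate"
      }
    },
    "possible_controls": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "experiment"
      }
    },
    "documents": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "document"
      }
    },
    "description": {
      "kind": "text"
    },
    "lab": {
      "kind": "link",
      "link_to": "lab"
    },
    "award": {
      "kind": "link",
      "link_to": "award"
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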