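{
  "type_name": "library",
  "schema_version": 1,
  "description": "Nucleic acid extracted from a biosample and prepared for sequencing.",
  "required": [
    "biosample",
    "nucleic_acid_term_name"
  ],
  "properties": {
    "biosample": {
      "kind": "link",
      "link_to": "biosample"
    },
    "nucleic_acid_term_name": {
      "kind": "text",
      "enum": [
        "DNA",
        "RNA",
        "polyadenylated mRNA",
        "rRNA-depleted RNA"
      ]
    },
    "spikeins_used": {
      "kind": "list",
      "items": {
        "kind": "text"
      },
      "description": "names of spike-in sets added for calibration"
    },
    "fragmentation_method": {
      "kind": "text"
    },
    "lysis_method": {
      "kind": "text"
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
  },
  "dependencies": {
    "nucleic_acid_term_name": {
      "trigger_values": [
        "DNA"
      ],
      "forbidden_fields": [
        "spikeins_used"
      ]
    }
  }
}
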