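{
  "type_name": "biosample",
  "schema_version": 1,
  "description": "One tube/batch/dissection of biological material used as assay input. The ontology term field depends on the sample type: UBERON for tissues, CL for primary cells, EFO for immortalized cell lines.",
  "required": [
    "biosample_term_name",
    "biosample_type",
    "donor",
    "source"
  ],
  "properties": {
    "biosample_term_name": {
      "kind": "text"
    },
    "biosample_type": {
      "kind": "text",
      "enum": [
        "tissue",
        "primary cell",
        "immortalized cell line"
      ]
    },
    "tissue_term": {
      "kind": "text",
      "pattern": "[A-Za-z]+:[0-9A-Za-z_]+",
      "description": "UBERON CURIE"
    },
    "cell_term": {
      "kind": "text",
      "pattern": "[A-Za-z]+:[0-9A-Za-z_]+",
      "description": "CL CURIE"
    },
    "cell_line_term": {
      "kind": "text",
      "pattern": "[A-Za-z]+:[0-9A-Za-z_]+",
      "description": "EFO CURIE"
    },
    "donor": {
      "kind": "link",
      "link_to": "donor"
    },
    "source": {
      "kind": "text",
      "description": "vendor or lab providing the material"
    },
    "date_obtained": {
      "kind": "text",
      "pattern": "[0-9]{4}-[0-9]{2}-[0-9]{2}"
    },
    "starting_amount": {
      "kind": "number",
      "description": "cells or mg of input material"
    },
    "treatments": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "treatment"
      }
    },
    "documents": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "document"
      }
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
    "biosample_type": [
      {
        "trigger_values": [
          "tissue"
        ],
        "required_fields": [
          "tissue_term"
        ]
      },
      {
        "trigger_values": [
          "primary cell"
        ],
        "required_fields": [
          "cell_term"
        ]
      },
      {
        "trigger_values": [
          "immortalized cell line"
        ],
        "required_fields": [
          "cell_line_term"
        ]
      }
    ]
  }
}
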