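{
  "type_name": "file",
  "schema_version": 1,
  "description": "Metadata for one data file: format, output type, provenance (derived_from), pairing for paired-end runs, and content md5sum. No file content is read.",
  "required": [
    "file_format",
    "output_type",
    "dataset",
    "md5sum"
  ],
  "properties": {
    "file_format": {
      "kind": "text",
      "enum": [
        "fastq",
        "bam",
        "bigWig",
        "bed",
        "tsv"
      ]
    },
    "output_type": {
      "kind": "text",
      "description": "short content description, e.g. reads, alignments, signal"
    },
    "dataset": {
      "kind": "link",
      "link_to": "experiment"
    },
    "replicate": {
      "kind": "link",
      "link_to": "replicate"
    },
    "derived_from": {
      "kind": "list",
      "items": {
        "kind": "link",
        "link_to": "file"
      }
    },
    "md5sum": {
      "kind": "text",
      "pattern": "[0-9a-f]{32}"
    },
    "run_type": {
      "kind": "text",
      "enum": [
        "single-ended",
        "paired-ended"
      ]
    },
    "paired_with": {
      "kind": "link",
      "link_to": "file"
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
    "file_format": {
      "trigger_values": [
        "fastq"
      ],
      "required_fields": [
        "run_type"
      ]
    },
    "run_type": {
      "trigger_values": [
        "paired-ended"
      ],
      "required_fields": [
        "paired_with"
      ]
    },
    "paired_with": {
      "required_fields": [
        "run_type"
      ]
    }
  }
}
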