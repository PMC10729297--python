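{
  "format": "RFC-4180 CSV, UTF-8, one table per file",
  "tables": {
    "oligos": {
      "columns": [
        "oligo_id",
        "name",
        "sequence"
      ],
      "optional": []
    },
    "parts": {
      "columns": [
        "part_id",
        "bin_id",
        "role",
        "sequence"
      ],
      "optional": []
    },
    "fragments": {
      "columns": [
        "fragment_id",
        "part_id",
        "length_bp",
        "left_overlap_bp",
        "right_overlap_bp",
        "template_id",
        "forward_oligo_id",
        "reverse_oligo_id",
        "sequence"
      ],
      "optional": [
        "sequence"
      ]
    },
    "constructs": {
      "columns": [
        "construct_id",
        "fragment_ids",
        "circular"
      ],
      "optional": [
        "circular"
      ]
    }
  },
  "notes": {
    "fragment_ids": "ordered, ';'-separated",
    "circular": "true/false, default true",
    "meta": "unknown columns are preserved verbatim on round-trip"
  }
}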