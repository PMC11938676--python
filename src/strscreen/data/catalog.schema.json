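{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "strscreen locus catalog",
  "version": "1.0",
  "type": "object",
  "required": [
    "loci"
  ],
  "properties": {
    "schema_version": {
      "type": "string"
    },
    "coordinate_system": {
      "enum": [
        "0-based-half-open",
        "1-based-closed"
      ],
      "default": "0-based-half-open"
    },
    "loci": {
      "type": "array",
      "items": {
        "$defs": {
          "MotifEntry": {
            "additionalProperties": true,
            "description": "One curated motif at a locus with its clinical classification.",
            "properties": {
              "motif": {
                "minLength": 1,
                "title": "Motif",
                "type": "string"
              },
              "orientation": {
                "default": "reference",
                "enum": [
                  "reference",
                  "gene"
                ],
                "title": "Orientation",
                "type": "string"
              },
              "class": {
                "default": "unknown",
                "enum": [
                  "benign",
                  "pathogenic",
                  "uncertain",
                  "unknown"
                ],
                "title": "Class",
                "type": "string"
              }
            },
            "required": [
              "motif"
            ],
            "title": "MotifEntry",
            "type": "object"
          }
        },
        "additionalProperties": true,
        "description": "One curated tandem-repeat disease locus.\n\nCoordinates are 0-based half-open per genome build. Thresholds\n(``benign_max``, ``intermediate_min``/``max``, ``pathogenic_min``/``max``)\nare in repeat units; ``pathogenic_min`` is the smallest allele size\nclassified as pathogenic. Unknown input fields are preserved (pydantic\n``extra=\"allow\"``) so a load -> serialize -> load round trip is lossless.",
        "properties": {
          "locus_id": {
            "title": "Locus Id",
            "type": "string"
          },
          "gene": {
            "title": "Gene",
            "type": "string"
          },
          "chrom": {
            "title": "Chrom",
            "type": "string"
          },
          "start_by_build": {
            "additionalProperties": {
              "type": "integer"
            },
            "title": "Start By Build",
            "type": "object"
          },
          "end_by_build": {
            "additionalProperties": {
              "type": "integer"
            },
            "title": "End By Build",
            "type": "object"
          },
          "strand": {
            "enum": [
              "+",
              "-"
            ],
            "title": "Strand",
            "type": "string"
          },
          "motif_len": {
            "minimum": 1,
            "title": "Motif Len",
            "type": "integer"
          },
          "reference_motif": {
            "title": "Reference Motif",
            "type": "string"
          },
          "motifs": {
            "items": {
              "$ref": "#/$defs/MotifEntry"
            },
            "title": "Motifs",
            "type": "array"
          },
          "locus_structure": {
            "default": "",
            "title": "Locus Structure",
            "type": "string"
          },
          "inheritance": {
            "enum": [
              "AD",
              "AR",
              "XLD",
              "XLR"
            ],
            "title": "Inheritance",
            "type": "string"
          },
          "benign_max": {
            "anyOf": [
              {
                "type": "integer"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Benign Max"
          },
          "intermediate_min": {
            "anyOf": [
              {
                "type": "integer"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Intermediate Min"
          },
          "intermediate_max": {
            "anyOf": [
              {
                "type": "integer"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Intermediate Max"
          },
          "pathogenic_min": {
            "minimum": 1,
            "title": "Pathogenic Min",
            "type": "integer"
          },
          "pathogenic_max": {
            "anyOf": [
              {
                "type": "integer"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Pathogenic Max"
          },
          "prevalence_fraction": {
            "anyOf": [
              {
                "maximum": 1.0,
                "minimum": 0.0,
                "type": "number"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Prevalence Fraction"
          },
          "prevalence_note": {
            "default": "",
            "title": "Prevalence Note",
            "type": "string"
          },
          "independent_observations": {
            "default": 0,
            "minimum": 0,
            "title": "Independent Observations",
            "type": "integer"
          },
          "onset_min_years": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Onset Min Years"
          },
          "onset_max_years": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Onset Max Years"
          },
          "typical_onset_min": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Typical Onset Min"
          },
          "typical_onset_max": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ],
            "default": null,
            "title": "Typical Onset Max"
          },
          "genomic_context": {
            "items": {
              "enum": [
                "coding",
                "5'UTR",
                "3'UTR",
                "intronic",
                "promoter",
                "intergenic"
              ],
              "type": "string"
            },
            "title": "Genomic Context",
            "type": "array"
          },
          "flags": {
            "items": {
              "enum": [
                "preliminary",
                "conflicting_evidence",
                "contraction_locus",
                "excluded_unreliable"
              ],
              "type": "string"
            },
            "title": "Flags",
            "type": "array",
            "uniqueItems": true
          }
        },
        "required": [
          "locus_id",
          "gene",
          "chrom",
          "strand",
          "motif_len",
          "reference_motif",
          "inheritance",
          "pathogenic_min"
        ],
        "title": "LocusRecord",
        "type": "object"
      }
    }
  }
}
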