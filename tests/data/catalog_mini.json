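{
  "schema_version": "1.0",
  "coordinate_system": "0-based-half-open",
  "description": "Synthetic six-locus test catalog. Gene symbols and threshold magnitudes follow well-known disease loci, but coordinates and curation fields are fabricated fixture values.",
  "loci": [
    {
      "locus_id": "HTT_HD",
      "gene": "HTT",
      "chrom": "chr4",
      "start_by_build": {"hg19": 3076603, "hg38": 3074876, "T2T-chm13": 3048332},
      "end_by_build": {"hg19": 3076660, "hg38": 3074933, "T2T-chm13": 3048389},
      "strand": "+",
      "motif_len": 3,
      "reference_motif": "CAG",
      "motifs": [
        {"motif": "CAG", "orientation": "reference", "class": "pathogenic"},
        {"motif": "CAA", "orientation": "reference", "class": "benign"}
      ],
      "locus_structure": "(CAG)n",
      "inheritance": "AD",
      "benign_max": 26,
      "intermediate_min": 27,
      "intermediate_max": 35,
      "pathogenic_min": 40,
      "prevalence_fraction": 0.0001215,
      "prevalence_note": "0.0106-0.0137%",
      "independent_observations": 120,
      "onset_min_years": 3,
      "onset_max_years": 85,
      "typical_onset_min": 30,
      "typical_onset_max": 50,
      "genomic_context": ["coding"]
    },
    {
      "locus_id": "FXN_FRDA",
      "gene": "FXN",
      "chrom": "chr9",
      "start_by_build": {"hg19": 71652202, "hg38": 69037286, "T2T-chm13": 81327459},
      "end_by_build": {"hg19": 71652220, "hg38": 69037304, "T2T-chm13": 81327477},
      "strand": "+",
      "motif_len": 3,
      "reference_motif": "GAA",
      "motifs": [
        {"motif": "GAA", "orientation": "reference", "class": "pathogenic"}
      ],
      "locus_structure": "(GAA)n",
      "inheritance": "AR",
      "benign_max": 33,
      "intermediate_min": 34,
      "intermediate_max": 65,
      "pathogenic_min": 66,
      "prevalence_fraction": 0.00002,
      "prevalence_note": "1 in 50,000",
      "independent_observations": 80,
      "onset_min_years": 5,
      "onset_max_years": 70,
      "typical_onset_min": 10,
      "typical_onset_max": 16,
      "genomic_context": ["intronic"]
    },
    {
      "locus_id": "DMD_DMD",
      "gene": "DMD",
      "chrom": "chrX",
      "start_by_build": {"hg19": 31302674, "hg38": 31284557},
      "end_by_build": {"hg19": 31302722, "hg38": 31284605},
      "strand": "-",
      "motif_len": 3,
      "reference_motif": "GAA",
      "motifs": [
        {"motif": "GAA", "orientation": "reference", "class": "pathogenic"}
      ],
      "locus_structure": "(GAA)n",
      "inheritance": "XLR",
      "pathogenic_min": 59,
      "prevalence_fraction": 0.0001,
      "prevalence_note": "< 1 per 10,000 males",
      "independent_observations": 1,
      "onset_min_years": 2,
      "onset_max_years": 10,
      "genomic_context": ["intronic"]
    },
    {
      "locus_id": "RFC1_CANVAS",
      "gene": "RFC1",
      "chrom": "chr4",
      "start_by_build": {"hg19": 39350044, "hg38": 39348424, "T2T-chm13": 41373344},
      "end_by_build": {"hg19": 39350099, "hg38": 39348479, "T2T-chm13": 41373399},
      "strand": "-",
      "motif_len": 5,
      "reference_motif": "AAAAG",
      "motifs": [
        {"motif": "AAAAG", "orientation": "reference", "class": "benign"},
        {"motif": "AAGGG", "orientation": "reference", "class": "pathogenic"},
        {"motif": "ACAGG", "orientation": "reference", "class": "uncertain"}
      ],
      "locus_structure": "(AAAAG)n",
      "inheritance": "AR",
      "pathogenic_min": 400,
      "independent_observations": 40,
      "onset_min_years": 19,
      "onset_max_years": 76,
      "typical_onset_min": 50,
      "typical_onset_max": 60,
      "genomic_context": ["intronic"]
    },
    {
      "locus_id": "VWA1_myopathy",
      "gene": "VWA1",
      "chrom": "chr1",
      "start_by_build": {"hg19": 1371178, "hg38": 1435798, "T2T-chm13": 1259845},
      "end_by_build": {"hg19": 1371198, "hg38": 1435818, "T2T-chm13": 1259865},
      "strand": "+",
      "motif_len": 10,
      "reference_motif": "GGCGCGGAGC",
      "motifs": [
        {"motif": "GGCGCGGAGC", "orientation": "reference", "class": "pathogenic"}
      ],
      "locus_structure": "(GGCGCGGAGC)n",
      "inheritance": "AR",
      "pathogenic_min": 3,
      "independent_observations": 6,
      "onset_min_years": 0,
      "onset_max_years": 12,
      "genomic_context": ["coding"],
      "flags": ["contraction_locus"]
    },
    {
      "locus_id": "POLG_PEO",
      "gene": "POLG",
      "chrom": "chr15",
      "start_by_build": {"hg38": 89333087},
      "end_by_build": {"hg38": 89333117},
      "strand": "-",
      "motif_len": 3,
      "reference_motif": "CAG",
      "motifs": [
        {"motif": "CAG", "orientation": "reference", "class": "pathogenic"}
      ],
      "locus_structure": "(CAG)n",
      "inheritance": "AD",
      "pathogenic_min": 15,
      "independent_observations": 25,
      "onset_min_years": 20,
      "onset_max_years": 60,
      "genomic_context": ["coding"]
    }
  ]
}
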