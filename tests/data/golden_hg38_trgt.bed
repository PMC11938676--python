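chr1	1435798	1435818	ID=VWA1_myopathy;MOTIFS=GGCGCGGAGC;STRUC=(GGCGCGGAGC)n
chr15	89333087	89333117	ID=POLG_PEO;MOTIFS=CAG;STRUC=(CAG)n
chr4	3074876	3074933	ID=HTT_HD;MOTIFS=CAG,CAA;STRUC=(CAG)n
chr4	39348424	39348479	ID=RFC1_CANVAS;MOTIFS=AAAAG,AAGGG,ACAGG;STRUC=(AAAAG)n
chr9	69037286	69037304	ID=FXN_FRDA;MOTIFS=GAA;STRUC=(GAA)n
chrX	31284557	31284605	ID=DMD_DMD;MOTIFS=GAA;STRUC=(GAA)n
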