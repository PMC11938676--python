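chr1	1435798	1435818	VWA1_myopathy
chr15	89333087	89333117	POLG_PEO
chr4	3074876	3074933	HTT_HD
chr4	39348424	39348479	RFC1_CANVAS
chr9	69037286	69037304	FXN_FRDA
chrX	31284557	31284605	DMD_DMD
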