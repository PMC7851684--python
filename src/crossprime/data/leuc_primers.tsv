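species	gene	orientation	sequence	tm	gc
Acetobacterium woodii	leuC1	upstream	CATACCTGTACTCATGGGGCTT	55.6	
Acetobacterium woodii	leuC1	downstream	CCGGCCTCGATCGCCATATT	55.1	
Acetobacterium woodii	leuC2	upstream	CATACCTGTACCTATGGTGCGC	57.1	
Acetobacterium woodii	leuC2	downstream	CCGGCTTCAATGGCCATATT	58.9	
Bacillus subtilis	leuC	upstream	TCGAAGTTGCGGTTAGAGGT	55.4	
Bacillus subtilis	leuC	downstream	ATCGGTTCCTGCACAAA	50.6	
Desulfovibrio vulgaris	leuC	upstream	CACACCTGCACCTACGGGGGGC	65.6	
Desulfovibrio vulgaris	leuC	downstream	CCCGCCTCGATGGCCATGTT	61.7	
Geoalkalibacter subterraneus	leuC	upstream	CACACCTGTACCCATGGGGCCT	62.3	
Geoalkalibacter subterraneus	leuC	downstream	CCGGCTTCGATGGCCATGTT	59.9	
Pseudomonas putida	leuC	upstream	TCGAAGTTGCGGTTGGAGGT	58.4	
Pseudomonas putida	leuC	downstream	ATCGGCTCGTGCACCAA	56.2	
Thauera aromatica	leuC	upstream	TCGAAGTTGCGGTTCGAGGT	58.5	
Thauera aromatica	leuC	downstream	ATCGGCTCGTGCACCAA	56.2	
MSA1	leuC	upstream	CAYACCTGYACYYAYGGKGSKY	51.1-66.0	
MSA1	leuC	downstream	CCSGCYTCRATSGCCATRTT	51.8-57.9	
MSA2	leuC	upstream	TCGAAGTTGCGGTTVGAGGT	51.8-53.8	
MSA2	leuC	downstream	ATCGGYTCSTGSACMAA	44.6-49.5	
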