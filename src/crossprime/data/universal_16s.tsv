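species	gene	orientation	sequence	tm	gc
universal	16S rRNA V4	upstream	GTGCCAGCMGCCGCGGTAA	62.6	
universal	16S rRNA V4	downstream	GGACTACHVGGGTWTCTAAT	48.9	
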