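species	gene	orientation	sequence	tm	gc
Acetobacterium woodii	emrB	upstream	CCTGTTTACATTGGGGTCGTT	54.8	48
Acetobacterium woodii	emrB	downstream	AACCAAAGATCCCAAGGCGA	55.9	50
Acetobacterium woodii	emrE	upstream	TTGCCTTGGGAATCATGATTCT	54.6	41
Acetobacterium woodii	emrE	downstream	GTGATGTTCGTGGACTGTTTTC	54.4	45
Acetobacterium woodii	matE1	upstream	CTGGCTGCCCTGACTAATAA	53.4	50
Acetobacterium woodii	matE1	downstream	GCGTTTCCGATCCAAATGAT	53.3	45
Acetobacterium woodii	matE2	upstream	AAATTGGAATCAACCAGGCG	53.4	45
Acetobacterium woodii	matE2	downstream	CGTCAATGTTTGGAGTAGCC	53.3	50
Acetobacterium woodii	mepA	upstream	CATTACTCTTTGGTGTCGGC	53.3	50
Acetobacterium woodii	mepA	downstream	GCGGTATAAGGGATCGCATA	53.5	50
Acetobacterium woodii	qacA	upstream	GCCGCCCCAACGAGTCCTTT	61.9	65
Acetobacterium woodii	qacA	downstream	GGGATGGGCGCCGGAATGTT	62.0	65
Bacillus subtilis	ebrA	upstream	TACTCCGATCACTGTCGTCAGC	58.0	55
Bacillus subtilis	ebrA	downstream	CCTCACGATTGCCATATGTTCGG	58.0	52
Bacillus subtilis	emrE	upstream	TTGACTGTGCTTTCTTTTTCGG	54.2	41
Bacillus subtilis	emrE	downstream	TGGTAAGAGACAATCCGCAAAA	54.4	41
Bacillus subtilis	lmrA	upstream	GATAAAATTCACGCGGCAGT	53.7	45
Bacillus subtilis	lmrA	downstream	CCGGGCGGTATTTTAAATGG	53.7	50
Bacillus subtilis	qacE1	upstream	CAGGTTTAAAGACACAACACCG	54.3	45
Bacillus subtilis	qacE1	downstream	ACAAAGCTTATTCCCAGTTTGC	53.9	41
Bacillus subtilis	qacE2	upstream	ATTATAGCTGCCATTGCCATGA	54.3	41
Bacillus subtilis	qacE2	downstream	GTGAAATCACCTGTGAAAGCTG	54.3	45
Desulfovibrio vulgaris	HAE1	upstream	CCCTACGACACCACCCGCTT	60.7	65
Desulfovibrio vulgaris	HAE1	downstream	GATGATGGCGTCGTCCACCA	59.0	60
Desulfovibrio vulgaris	HAE2	upstream	AATGTGTTGATGGAGAAGCCC	54.8	48
Desulfovibrio vulgaris	HAE2	downstream	ATCCCCTACGACACCACCAA	56.8	55
Desulfovibrio vulgaris	norM	upstream	ACGGCCTGCCCAGCGGCATC	66.8	75
Desulfovibrio vulgaris	norM	downstream	GCTGCCCTTGCCCATGGCCT	64.4	70
Desulfovibrio vulgaris	qacA/emrB	upstream	AGAAGATCCACCGCCAGGTG	58.3	60
Desulfovibrio vulgaris	qacA/emrB	downstream	TCCTGTTCCGCATTTTTCAGG	55.4	48
Geoalkalibacter subterraneus	acrB2	upstream	TGAAGTCCTGCCGCCAGTCAT	60.9	59
Geoalkalibacter subterraneus	acrB2	downstream	GCGTAAAAAGTCACCGGCACCA	60.3	55
Geoalkalibacter subterraneus	acrB1	upstream	AGGAACGCCTTTTGGATGACGC	60.1	55
Geoalkalibacter subterraneus	acrB1	downstream	CCCTGGCAGGTCAGACCAAGAA	60.2	59
Geoalkalibacter subterraneus	acrB3	upstream	GCCGCATGAACCTGCTGATCAA	60.2	55
Geoalkalibacter subterraneus	acrB3	downstream	CACACCCAGCGCCATGATGAAG	60.5	59
Geoalkalibacter subterraneus	sugE	upstream	TAGCCGGATTATTTGAAGTCG	52.2	43
Geoalkalibacter subterraneus	sugE	downstream	CCGAAAAGAATAATCCCGAGAA	52.4	41
Geoalkalibacter subterraneus	HAE1	upstream	ACATTTTCCACCACCACAAT	52.1	40
Geoalkalibacter subterraneus	HAE1	downstream	ATTCCCTACGATACCACCAA	52.0	45
Geoalkalibacter subterraneus	HAE2	upstream	CCCTATGACACCACGCCTTT	56.4	55
Geoalkalibacter subterraneus	HAE2	downstream	CACGATGGCGTCATCCACCA	59.3	60
Pseudomonas putida	emrB	upstream	AGAAGATCCATGGCCAGCTG	56.2	55
Pseudomonas putida	emrB	downstream	TGGGCTTTCGTGTCTTGCAGG	59.7	57
Pseudomonas putida	emrB/qacA	upstream	GATCACCTCGCCAATCTGCA	56.9	55
Pseudomonas putida	emrB/qacA	downstream	CTGGTCAGCCTGATCACCTT	55.7	55
Pseudomonas putida	norM	upstream	TGGGCCTGCCGATTGGCGGT	65.9	70
Pseudomonas putida	norM	downstream	GTTGCCAGCGCCGTAGTACA	59.6	60
Pseudomonas putida	mexB	upstream	AAATCGGTGCCCAGGAATACCA	58.1	50
Pseudomonas putida	mexB	downstream	TGTTGATGACCTGCTCGATCGA	57.9	50
Pseudomonas putida	sugE	upstream	GACTCGCCGAACAGAATGAT	54.6	50
Pseudomonas putida	sugE	downstream	TGTCCTGGATCATCCTGTTTTT	53.7	41
Pseudomonas putida	qacA1/3	upstream	AGAASAYCCAGCGCCACGAM	58.3-61.8	55-65
Pseudomonas putida	qacA1	downstream	TGCTGGCCCGTGTACTGCAGG	63.5	67
Pseudomonas putida	qacA3	downstream	TCGTAATCCGGGTGATCCAGG	57.6	57
Pseudomonas putida	qacA4	upstream	CGCGTGGTGCAGGGCCTGGG	67.3	80
Pseudomonas putida	qacA4	downstream	CCAAGCAGGCCGACTGGCAGG	64.4	71
Pseudomonas putida	acrB/mexD	upstream	TGGYGGCGCWGTACGAAAGC	60.1-62.8	60-65
Pseudomonas putida	acrB	downstream	TTGGCGAACGCCACCATCAGGAT	63.5	57
Shared	Taro_acrB2/Pputi_mexD	downstream	TTGGCGAACTCSAYGATCAGGAT	58.1-60.2	48-52
Thauera aromatica	acrB1	upstream	CTACATCGTCGTACCGTGGGCA	60.5	59
Thauera aromatica	acrB1	downstream	ATCAGCGAGACCGTCATCAGCA	60.2	55
Thauera aromatica	acrB2	upstream	TGGCAGCGCAGTTCGAGAGC	62.2	65
Thauera aromatica	acrB4/acrB6/acrB7	upstream	ACCARCAWGCCGAGCGCGAT	61.9-64.1	60-65
Thauera aromatica	acrB4	downstream	GGGCATGGAGCTGAACGTGGT	62.5	62
Thauera aromatica	acrB6	downstream	CGGCATCCGCCTCGAGCGCGT	69.5	76
Thauera aromatica	acrB7	downstream	GGGCGTGCAGCTGCGCCTGAT	68.0	71
Thauera aromatica	acrB3/acrB5	upstream	AGCGCGATSATGCCGAYCAT	60.5-61.5	55-60
Thauera aromatica	acrB3	downstream	AGTTGCTGTGGGGCGGCGAG	64.3	70
Thauera aromatica	acrB5	downstream	AGTTGAAGTGGGACGGCGAG	59.8	60
Thauera aromatica	norM	upstream	TCGGCCTGCCGATGGGGGTG	65.6	75
Thauera aromatica	norM	downstream	GTCCTGCGCGCCGGCCGACT	69.0	80
Thauera aromatica	HAE1	upstream	CCCTACGACACCACGCCCTT	60.7	65
Thauera aromatica	HAE1	downstream	CACGATGGCGTCGTCCACCA	61.6	65
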