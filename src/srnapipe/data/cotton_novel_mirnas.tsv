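name	mature	gene_id	lm	arm	lp	gc_percent	star	delta_g	mfei
miR1327	TGAATATTGTTAAAGTAGAAA	Unigene15286	21	3'	122	27.87	TCTACTTTAACAATATTCATA	-43.30	1.27
miR1335	TGAAGCTGCCACATGATCTAG	Unigene16386	21	5'	103	46.60	AGATCATGCTGGCAGCTTCAAC	-50.20	1.05
miR1336	TCTTTCCTACTCCTCCCATTCC	CL1064.Contig1	22	3'	105	39.05	AAGTGGGATGGGTGGAAAGATT	-44.50	1.09
miR1337	AATGGAGGAGTTGGAAAGATT	Unigene26231	21	5'	95	28.42	TTTCCAATTCCTCCCATTCCAC	-36.70	1.36
miR1338	AATGAGTTAGGCGAGAGGTTC	CL5909.Contig2	21	3'	169	31.36	CTCTGGTTTAACTCATTTGTA	-51.10	0.96
miR1339	AAAAGCAATGAAGAACGACCT	CL5831.Contig1	21	3'	102	38.24	GCTGCGTTCTTCATTGCTTAACA	-41.30	1.06
miR1340	ACCGGCCGGGGGACGGACTGGG	CL6985.Contig2	22	3'	119	65.55	CAGTCCCGAACCCGTCAGCTGC	-62.60	0.80
miR1341	CTTTTTATAGGATAGGGACTG	Unigene30026	21	3'	103	29.13	GTTCCTATCTTATTAAAAAGAA	-37.10	1.24
miR1342	TGAAGCTGCAAGATGATCTGA	CL8098.Contig4	21	5'	262	34.35	AGATCATGCTGGCAGCTTCAAC	-57.70	0.64
miR1343	CAGAGATCGTCAAAGCATATC	CL1118.Contig5	21	5'	94	37.23	TATGCTTTGACGATCTCTGAT	-60.90	1.74
miR1344	TTTGCATGAACTAGGAGACGT	Unigene10644	21	3'	105	54.29	CGGCTGCTAGTTCATGGATGCC	-45.60	0.80
miR1345	AAGCGGAAGCTGAATTAGTTG	Unigene14674	21	3'	76	43.42	GAAACTAATCGAGCTCCGTTTGA	-26.00	0.79
miR1346	GCTGCCATCTCATGCATTCGG	Unigene20900	21	5'	165	44.85	CGATGCATGGCATGGGAGCACCA	-59.10	0.80
miR1347	TACAGCTTTAGAAATCATCCCT	Unigene13628	22	5'	109	29.36	GGATGATTTCTAAAGCTCTAGA	-48.40	1.51
miR1348	AGTGTCTGGGTGGTGTAGTTGGT	Unigene4349	23	5'	83	50.60	CCATTCGAACACGGGCTCAGACATTT	-23.90	0.65
miR1349	TAACTTGTCTTCGCCCTTCTC	Unigene8023	21	3'	201	34.83	GAAGTGCATGGCAAGTTAGA	-48.70	0.70
miR1350	TGGCACGGCTCAATCAAATTA	Unigene7762	21	5'	89	38.20	ATTTGATTGAGCCATTCCAAC	-34.60	1.02
miR1351	ACTCATAATTTAGCAAAGTCG	Unigene8111	21	3'	129	28.68	TTGCTGGATTATGAGTCTAAT	-61.40	1.66
miR1352	AATGCTTGAGGTGATAGGTTCA	Unigene14827	22	5'	137	50.37	AACCATTGCCTCAAGCACTTG	-58.80	0.85
miR1353	AAGGCAAAGGAAGAAAAGAGTGA	CL9674.Contig1	23	5'	105	38.10	ACTCTTTTTTTCCTGCCTTGC	-45.90	1.15
miR1354	AAAGTGGATGAAATTTTTAGC	Unigene26528	21	3'	159	36.48	TAAAAATTTCATTCATTTCTA	-66.10	1.14
miR1355	ATGCACTGCCTCTTCCCTGGC	Unigene10226	21	3'	102	53.92	AACAGGCTGAGCATGGATGGA	-43.40	0.79
miR1356	AACTGTGAAGCTATAAGGTAT	Unigene19434	21	5'	110	37.27	ACTTTTGTTTCACATTAC	-23.90	0.65
miR1357	AAGCTGTTGATGGCCGGCATGA	CL9715.Contig1	22	5'	91	46.15	ATGCCTATCATCAGGAGACTCT	-30.30	0.72
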