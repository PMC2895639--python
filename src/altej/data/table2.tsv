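table_id	row_id	genotype	paper_class	field_5prime	field_mid	field_3prime	n_isolates	footnote_flags
table2	r01	mus308_D5_2003	short_mh	acccagacCATGATGAAATAA	(CAT)	CATGacccagac	2	-
table2	r02	mus308_D5_2003	short_mh	acccagacCATG	(ATG)	TTATTTCATCATGacccagac	1	-
table2	r03	mus308_D5_2003	short_mh	acccagacCATGATGAAATAAC	(AT)	GTTATTTCATCATGacccagac	5	-
table2	r04	mus308_D5_2003	short_mh	acccagacCATGATGAAATAACA	(TA)	TGTTATTTCATCATGacccagac	2	-
table2	r05	mus308_D5_2003	blunt	acccagacCATGATGAAATAACATA	-	TTATTTCATCATGacccagac	1	-
table2	r06	mus308_D5_2003	small_insertion	acccagacCATGATGAAATAACAT	G	TGTTATTTCATCATGacccagac	1	-
table2	r07	mus308_D5_2003	small_insertion	acccagacCATGATGAAATAACATA	AC	ATGTTATTTCATCATGacccagac	1	-
table2	r08	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACAT	GTTA	TATGTTATTTCATCATGacccagac	1	-
table2	r09	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACATA	TGTA	TATGTTATTTCATCATGacccagac	1	-
table2	r10	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACA	GTGAA	ATGTTATTTCATCATGacccagac	1	-
table2	r11	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACAT	GTTATGT	TATGTTATTTCATCATGacccagac	1	-
table2	r12	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACAT	GTTATACA	TATGTTATTTCATCATGacccagac	1	-
table2	r13	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACATA	TATGTTATAACA	TATGTTATTTCATCATGacccagac	1	-
table2	r14	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAA	TCATGTTATTTC	ATGTTATTTCATCATGacccagac	1	-
table2	r15	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACATA	TAACATGAATAAC	ATGTTATTTCATCATGacccagac	1	-
table2	r16	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACATA	TATAATGTTATAACATATAACATATGTTATGAAATAATAACA	TATGTTATTTCATCATGacccagac	1	-
table2	r17	mus308_D5_2003	large_insertion	acccagacCATGATGAAATAACAT	CATCATTTATCATTTATTATTATTATTATTTATTATTATTTATTATTTA	TTATTTCATCATGacccagac	1	-
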