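table_id	row_id	genotype	paper_class	field_5prime	field_mid	field_3prime	n_isolates	footnote_flags
table1	r01	spnA	long_mh	acccagac	(CATgATGA)	cccagac	14	imperfect_mh
table1	r02	spnA	long_mh	acccagac	(CATGA)	cccagac	4	-
table1	r03	spnA	long_mh	none	(TGACCCAGAC)	-	2	past_target_deletion
table1	r04	spnA	short_mh	acccagacCATG	(ATG)	TTATTTCATCATGacccagac	1	-
table1	r05	spnA	short_mh	acccagacCA	(TGA)	cccagac	1	discordant
table1	r06	spnA	short_mh	acccagacCATGATGAAATAA	(CAT)	Gacccagac	3	-
table1	r07	spnA	short_mh	acccagacCATGATGAAATAAC	(AT)	GTTATTTCATCATGacccagac	14	-
table1	r08	spnA	short_mh	acccagacCATGATGAAATAACA	(TA)	TGTTATTTCATCATGacccagac	5	-
table1	r09	spnA	short_mh	acccagacCATGATGAAA	(TA)	TGTTATTTCATCATGacccagac	1	-
table1	r10	spnA	short_mh	acccagacCATGATGAA	(AT)	GTTATTTCATCATGacccagac	1	-
table1	r11	spnA	short_mh	none	(T)	TCATGacccagac	1	past_target_deletion
table1	r12	spnA	blunt	acccagacCATGATGAAATA	-	TTATTTCATCATGacccagac	1	-
table1	r13	spnA	small_insertion	acccagacCATGATGAAATAACATA	A	CATCATGacccagac	1	-
table1	r14	spnA	small_insertion	acccagacCATGATGA	G	CATCATGacccagac	1	-
table1	r15	spnA	small_insertion	acccagacCATGATGAAATAACATA	AC	ATGTTATTTCATCATGacccagac	3	-
table1	r16	spnA	small_insertion	acccagacCATGATGAAATAACAT	GT	TATGTTATTTCATCATGacccagac	1	-
table1	r17	spnA	small_insertion	acccagacCATGATGA	AC	ATGTTATTTCATCATGacccagac	1	discordant
table1	r18	spnA	small_insertion	acccagacCA	AG	ATGacccagac	1	-
table1	r19	spnA	small_insertion	acccagacCATGATGAAATAACATA	TTC	ATGTTATTTCATCATGacccagac	1	-
table1	r20	spnA	large_insertion	acccagacCATGATGAAATAACAT	GTTA	TATGTTATTTCATCATGacccagac	1	-
table1	r21	spnA	large_insertion	acccagacCATGATGAAATAACATA	TTTAT	TGTTATTTCATCATGacccagac	1	-
table1	r22	spnA	large_insertion	acccagacCATGATGAAATAACAT	TTATCA	TGTTATTTCATCATGacccagac	1	discordant
table1	r23	spnA	large_insertion	acccagacCATGATGAAATAACAT	TTAACATAAC	ATGTTATTTCATCATGacccagac	1	-
table1	r24	spnA	large_insertion	acccagacCATGATGAAATAACATA	TTATTATTATA	TTATTTCATCATGacccagac	1	-
table1	r25	spnA	large_insertion	acccagacCATGATGAAATAACAT	GAAATAATAAC	ATGTTATTTCATCATGacccagac	1	-
table1	r26	spnA	large_insertion	acccagacCATGATGAAATAACAT	GTATTACATAAC	ATGTTATTTCATCATGacccagac	1	-
table1	r27	spnA	large_insertion	acccagacCATGATGAAATAA	TAATAATAATATAA	TATGTTATTTCATCATGacccagac	1	-
table1	r28	spnA	large_insertion	acccagacCATGATGAAATA	TCATGAAATATCATA	TCATCATGacccagac	1	-
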