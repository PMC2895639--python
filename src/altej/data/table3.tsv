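table_id	row_id	genotype	paper_class	field_5prime	field_mid	field_3prime	n_isolates	footnote_flags
table3	r01	mus308_D2_2003	long_mh	acccagac	(CATgATGA)	cccagac	1	imperfect_mh
table3	r02	mus308_D2_2003	short_mh	acccagacCATGATGAAATAAC	(AT)	GTTATTTCATCATGacccagac	7	-
table3	r03	mus308_D2_2003	short_mh	acccagacCATGATGAAATAACA	(TA)	TGTTATTTCATCATGacccagac	3	-
table3	r04	mus308_D2_2003	short_mh	acccagacCATGATGA	(AT)	GTTATTTCATCATGacccagac	1	discordant
table3	r05	mus308_D2_2003	short_mh	acccagacCATGATGAAATAACA	(T)	TATTTCATCATGacccagac	1	-
table3	r06	mus308_D2_2003	blunt	acccagacCATGATGAAATAACATA	-	TATGTTATTTCATCATGacccagac	1	-
table3	r07	mus308_D2_2003	blunt	acccagacCATGATGAAATAACAT	-	TATGTTATTTCATCATGacccagac	1	-
table3	r08	mus308_D2_2003	small_insertion	acccagacCATGATGAAATAACAT	T	TATGTTATTTCATCATGacccagac	1	-
table3	r09	mus308_D2_2003	small_insertion	acccagacCATGATGAAATAACATA	CA	ATGTTATTTCATCATGacccagac	1	-
table3	r10	mus308_D2_2003	small_insertion	acccagacCATGATGAAATAACATA	AC	ATGTTATTTCATCATGacccagac	1	-
table3	r11	mus308_D2_2003	small_insertion	acccagacCATGATGAAATAACATA	TA	TATGTTATTTCATCATGacccagac	1	-
table3	r12	mus308_D2_2003	small_insertion	acccagacCATGATGAAATAA	TGT	TATGTTATTTCATCATGacccagac	1	-
table3	r13	mus308_D2_2003	small_insertion	acccagacCATGATGAAATAACATA	TGT	TATGTTATTTCATCATGacccagac	2	-
table3	r14	mus308_D2_2003	large_insertion	acccagacCATGATGAAATAACATA	ACATAA	ATGTTATTTCATCATGacccagac	1	-
table3	r15	mus308_D2_2003	large_insertion	acccagacCATGATGAAATAACATA	TATACCG	TATGTTATTTCATCATGacccagac	1	-
table3	r16	mus308_D2_2003	large_insertion	acccagacCATGATGAAATAACATA	TGTTATAAC	ATGTTATTTCATCATGacccagac	1	-
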