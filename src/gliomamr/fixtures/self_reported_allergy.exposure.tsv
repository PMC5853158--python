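# self_reported_allergy (exposure side): per-SNP summary associations, GRCh37
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs10189699	2q12.1	102879464	C	A	0.857	1.16	1.12	1.20
rs10497813	2q33.1	198914072	G	T	0.599	1.08	1.05	1.11
rs9860547	3q28	188128979	A	G	0.272	1.08	1.05	1.11
rs2101521	4p14	38811551	G	A	0.525	1.15	1.12	1.18
rs17388568	4q27	123329369	A	G	0.141	1.08	1.05	1.11
rs7720838	5p13.1	40486896	T	G	0.362	1.08	1.06	1.11
rs1438673	5q22.1	110467499	C	T	0.296	1.12	1.09	1.15
rs9266772	6p21.33	31352113	C	T	0.175	1.11	1.08	1.14
rs7032572	9p24.1	6172380	G	A	0.114	1.12	1.08	1.16
rs962993	10p14	9053132	C	T	0.894	1.07	1.05	1.10
rs2155219	11q13.5	76999194	T	G	0.532	1.11	1.09	1.14
rs17228058	15q22.33	67450305	G	A	0.100	1.08	1.05	1.11
rs9303280	17q21.1	38074031	C	T	0.654	1.07	1.05	1.09
rs6021270	20q13.2	50141264	T	C	0.346	1.16	1.10	1.22
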