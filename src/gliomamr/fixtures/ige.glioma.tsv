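# ige (glioma side): per-SNP summary associations, GRCh37
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs2251746	1q23.2	159272060	T	C		0.98	0.95	1.02
rs20541	5q31.1	131995964	G	A		1.01	0.97	1.06
rs2571391	6p22.1	29923838	A	C		0.97	0.94	1.01
rs2858331	6p21.32	32681277	G	A		1.02	0.98	1.06
rs1059513	12q13.3	57489709	T	C		0.97	0.92	1.03
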