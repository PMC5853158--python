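# ige (exposure side): per-SNP summary associations, GRCh37
# exposure effect scale: exp(beta) per SD of serum IgE
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs2251746	1q23.2	159272060	T	C	0.985	1.09	1.08	1.11
rs20541	5q31.1	131995964	G	A	0.730	1.08	1.06	1.10
rs2571391	6p22.1	29923838	A	C	0.697	1.06	1.05	1.08
rs2858331	6p21.32	32681277	G	A	0.490	1.04	1.03	1.06
rs1059513	12q13.3	57489709	T	C	0.930	1.13	1.09	1.17
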