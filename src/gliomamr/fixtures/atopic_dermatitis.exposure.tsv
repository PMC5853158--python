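# atopic_dermatitis (exposure side): per-SNP summary associations, GRCh37
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs11205006	1q21.3	152440176	A	T	0.265	1.62	1.48	1.77
rs2228145	1q21.3	154426970	C	A	0.293	1.15	1.10	1.20
rs10199605	2p25.1	8495097	G	A	0.756	1.04	1.03	1.06
rs112111458	2p13.3	71100105	A	G	0.776	1.08	1.05	1.10
rs6720763	2q24.3	167992286	C	T	0.320	1.29	1.18	1.41
rs10214237	5p13.2	35883734	T	C	0.824	1.06	1.05	1.08
rs1295686	5q31.1	131995843	T	C	0.422	1.35	1.22	1.49
rs12153855	6p21.32	32074804	C	T	0.125	1.58	1.40	1.78
rs6473227	8q21.13	81285892	C	A	0.527	1.06	1.05	1.08
rs10738626	9p21.3	22373457	T	C	0.603	1.23	1.15	1.32
rs6602364	10p15.1	6038853	C	G	0.508	1.05	1.03	1.07
rs10791824	11q13.1	65559266	G	A	0.490	1.15	1.12	1.19
rs7127307	11q24.3	128187383	T	C	0.512	1.09	1.07	1.11
rs7130588	11q13.5	76270683	A	G	0.784	1.29	1.20	1.38
rs2143950	14q13.2	35572357	T	C	0.215	1.08	1.06	1.10
rs2041733	16p13.13	11229589	T	C	0.496	1.09	1.06	1.11
rs2164983	19p13.2	8789381	A	C	0.169	1.16	1.10	1.22
rs909341	20q13.33	62328742	C	T	0.738	1.32	1.21	1.44
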