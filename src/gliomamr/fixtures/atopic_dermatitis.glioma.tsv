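# atopic_dermatitis (glioma side): per-SNP summary associations, GRCh37
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs11205006	1q21.3	152440176	A	T		0.96	0.91	1.02
rs2228145	1q21.3	154426970	C	A		0.99	0.96	1.03
rs10199605	2p25.1	8495097	G	A		1.01	0.97	1.05
rs112111458	2p13.3	71100105	A	G		0.98	0.92	1.03
rs6720763	2q24.3	167992286	C	T		1.02	0.97	1.06
rs10214237	5p13.2	35883734	T	C		0.98	0.94	1.02
rs1295686	5q31.1	131995843	T	C		0.99	0.95	1.03
rs12153855	6p21.32	32074804	C	T		0.97	0.92	1.03
rs6473227	8q21.13	81285892	C	A		0.98	0.94	1.02
rs10738626	9p21.3	22373457	T	C		0.96	0.93	1.00
rs6602364	10p15.1	6038853	C	G		1.03	0.99	1.07
rs10791824	11q13.1	65559266	G	A		0.99	0.95	1.02
rs7127307	11q24.3	128187383	T	C		0.99	0.95	1.03
rs7130588	11q13.5	76270683	A	G		1.02	0.98	1.06
rs2143950	14q13.2	35572357	T	C		1.01	0.97	1.06
rs2041733	16p13.13	11229589	T	C		0.97	0.94	1.01
rs2164983	19p13.2	8789381	A	C		0.95	0.90	1.00
rs909341	20q13.33	62328742	C	T		1.32	1.26	1.37
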