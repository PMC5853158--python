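# asthma_hayfever (glioma side): per-SNP summary associations, GRCh37
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs10197862	2q12.1	102966549	A	G		0.98	0.93	1.03
rs4833095	4p14	38799710	T	C		1.03	0.99	1.08
rs1837253	5q22.1	110401872	C	T		0.96	0.93	1.00
rs7009110	8q21.13	81291879	T	C		0.98	0.94	1.01
rs72699186	9p24.1	6175855	T	A		0.97	0.93	1.02
rs2155219	11q13.5	76299194	T	G		1.01	0.97	1.05
rs17294280	15q22.33	67468285	G	A		0.98	0.94	1.03
rs62026376	16p13.13	11228712	C	T		0.97	0.93	1.01
rs7212938	17q21.1	38122680	G	T		1.00	0.97	1.04
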