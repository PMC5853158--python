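# asthma_hayfever (exposure side): per-SNP summary associations, GRCh37
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs10197862	2q12.1	102966549	A	G	0.839	1.24	1.16	1.32
rs4833095	4p14	38799710	T	C	0.425	1.20	1.14	1.26
rs1837253	5q22.1	110401872	C	T	0.618	1.17	1.11	1.23
rs7009110	8q21.13	81291879	T	C	0.533	1.14	1.09	1.19
rs72699186	9p24.1	6175855	T	A	0.110	1.26	1.17	1.36
rs2155219	11q13.5	76299194	T	G	0.532	1.17	1.13	1.21
rs17294280	15q22.33	67468285	G	A	0.120	1.18	1.12	1.25
rs62026376	16p13.13	11228712	C	T	0.856	1.17	1.11	1.23
rs7212938	17q21.1	38122680	G	T	0.473	1.16	1.11	1.22
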