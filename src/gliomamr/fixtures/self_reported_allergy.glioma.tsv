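# self_reported_allergy (glioma side): per-SNP summary associations, GRCh37
snp_id	region	position	effect_allele	other_allele	eaf	or	ci_lower	ci_upper
rs10189699	2q12.1	102879464	C	A		0.99	0.94	1.04
rs10497813	2q33.1	198914072	G	T		0.99	0.96	1.03
rs9860547	3q28	188128979	A	G		1.02	0.98	1.06
rs2101521	4p14	38811551	G	A		1.02	0.98	1.07
rs17388568	4q27	123329369	A	G		1.01	0.97	1.05
rs7720838	5p13.1	40486896	T	G		1.02	0.99	1.06
rs1438673	5q22.1	110467499	C	T		0.97	0.94	1.01
rs9266772	6p21.33	31352113	C	T		1.03	0.98	1.08
rs7032572	9p24.1	6172380	G	A		0.97	0.93	1.02
rs962993	10p14	9053132	C	T		1.02	0.98	1.06
rs2155219	11q13.5	76999194	T	G		1.01	0.97	1.05
rs17228058	15q22.33	67450305	G	A		1.00	0.96	1.04
rs9303280	17q21.1	38074031	C	T		0.98	0.94	1.02
rs6021270	20q13.2	50141264	T	C		1.02	0.94	1.10
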