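patient_id	sex	age_years	phenotype	allele1	allele2	extra_copy	lrs_allele1	lrs_allele2	conv_allele1	conv_allele2	genotype_group	notes
1	M	0.08	SW	micro:I2G	cahx:CH2		I2G	del (CAH-X-CH2)	I2G	Exon 1-10 Del	A
2	M	0.17	SW	micro:I2G	novel:c.292+1G>A		I2G	c.292 + 1G > A	I2G	c.292 + 1G>A	D
3	M	0.08	SW	micro:p.R357W	chimera:CH1		p.R357W	UTR5, exon 1-3 (CH1)	p.R357W	Exon 1-3 Del	Null
4	M	0.04	SW	del:solo	cahx:CH1		del (CYP21A2)	del (CAH-X-CH1)	Exon 1-10 Del	Exon 1-10 Del	Null
5	M	0.25	SW	micro:I2G	micro:I2G		I2G	I2G	I2G	I2G	A
6	M	0.06	SW	novel:p.E247Gfs*11	chimera:CH2		p.E247Gfs*11	UTR5, exon 1-5 (CH2)	p.E247Gfs*11	Exon 1-4 Del	D
7	F	1.33	SV	micro:p.I173N	cahx:CH3		p.I173N	del (CAH-X-CH3)	p.I173N	Exon 1-10 Del	B
8	F	0.08	SV	dup:E7E8[p.V282L,p.L308Ffs*6,p.Q319X]	chimera:CH4	intact	Exon 7-8 integration (p.V282L, p.L308Ffs*6, p.Q319X)	UTR5, exon 1 (CH4)	p.L308Ffs*, p.Q319X	p.P31L	C
9	M	0.05	SW	chimera:CH8	cahx:CH1		UTR5, exon 1-8 (CH8)	del (CAH-X-CH1)	Exon 1-10 Del	Exon 1-10 Del	Null
10	M	0.04	SW	micro:I2G	chimera:CH3		I2G	UTR5, part of exon 1-8 (CH3)	I2G	Exon 1-7 Del	A
11	M	0.08	SW	micro:I2G	cahx:CH2		I2G	del (CAH-X-CH2)	I2G	Exon 1-10 Del	A
12	M	0.08	SW	dup:E7E8[p.V282L,p.L308Ffs*6,p.Q319X]	chimera:CH1	intact	Exon 7-8 integration (p.V282L, p.L308Ffs*6, p.Q319X)	UTR5, exon 1-3 (CH1)	p.L308Ffs*, p.Q319X	Exon 1-3 Del	C
13	M	5.25	SV	micro:p.I173N	chimera:CH6		p.I173N	UTR5, part of exon 1-3, including I2G, excluding del 8 bp (CH6)	p.I173N	I2G	B
14	M	8.33	NC	micro:p.P31L	del:solo		p.P31L	del (CYP21A2)	p.P31L	Exon 1-10 Del	C
15	F	3.08	SV	micro:I2G	chimera:CH1		I2G	UTR5, exon 1-3 (CH1)	I2G	Exon 1-3 Del	A
16	F	0.17	SW	micro:I2G	del:solo		I2G	del (CYP21A2)	I2G	Exon 1-10 Del	A
17	M	0.06	SW	micro:I2G	micro:p.R357W		I2G	p.R357W	I2G	p.R357W	A
18	F	0.06	SW	micro:I2G	micro:I2G		I2G	I2G	I2G	I2G	A
19	M	0.58	SW	micro:I2G	micro:I2G		I2G	I2G	I2G	I2G	A
20	M	0.04	SW	micro:p.I173N	micro:p.I173N		p.I173N	p.I173N	p.I173N	p.I173N	B
21	M	4.83	SV	micro:I2G	micro:p.I173N		I2G	p.I173N	I2G	p.I173N	B
22	M	0.17	SW	micro:p.R357W	novel:p.R484Pfs*58		R357W	p.R484Pfs*58	p.R357W	p.R484Pfs	Null
23	M	0.08	SW	micro:I2G	novel:p.S126X		I2G	p.S126X	I2G	p.S126X	D
24	F	3.92	SV	micro:p.I173N	chimera:CH1		p.I173N	UTR5, exon 1-3(CH1)	p.I173N	Exon 1-3 Del	B
25	F	4.08	SV	micro:I2G	micro:p.I173N		I2G	p.I173N	I2G	p.I173N	B
26	F	0.08	SV	micro:p.I173N	novel:p.V306F		p.I173N	p.V306F	p.I173N	p.V306F	D
27	M	11.5	SV	micro:p.I173N	cahx:CH1		p.I173N	del (CAH-X-CH1)	p.I173N	Exon 1-10 Del	B
28	F	5.33	SV	micro:p.P31L	novel:p.R484Pfs*58		p.P31L	R484Pfs*58	p.P31L	p.R484Pfs	C
29	M	0.17	SW	micro:p.R357W	chimera:CH1		p.R357W	UTR5, exon 1-3 (CH1)	p.R357W	Exon 1-3 Del	Null
30	M	0.5	SW	micro:I2G	novel:p.G423_C424delinsVCL		I2G	p.G423_C424delinsVCL	I2G	p.G423_C424delinsVCL	D
31	F	4.67	SV	novel:p.R484Pfs*58	micro:p.I173N		p.R484Pfs*58	p.I173N	In vitro fertilization from sperm bank	p.I173N	B	donor-sperm IVF; allele origin not resolvable without the paternal genome
32	M	0.05	SW	micro:p.Q319X	cahx:CH1		p.Q319X	del (CAH-X-CH1)	p.Q319X	Exon 1-10 Del	Null
33	F	2.91	SV	micro:I2G	micro:p.I173N		I2G	p.I173N	I2G	p.I173N	B
34	M	3.33	SW	micro:p.I173N	novel:c.292+1G>A		p.I173N	c.292 + 1G > A	p.I173N	c.292 + 1G > A	D
35	M	0.17	SW	micro:I2G	novel:p.R355H		I2G	p.R355H	I2G	p.R355H	D
36	M	0.07	SV	micro:I2G	micro:p.I173N		I2G	p.I173N	I2G	p.I173N	B
37	F	3.17	SV	micro:p.G111Vfs*21	micro:p.I173N		p.G111Vfs*21	p.I173N	p.G111Vfs*21	p.I173N	B
38	M	0.08	SW	micro:I2G	novel:p.S126X		I2G	p.S126X	I2G	p.S126X	D
39	M	0.32	SW	micro:p.I173N	novel:p.R484Pfs*58		p.I173N	p.R484Pfs*58	p.I173N	p.R484Pfs	B
40	M	0.08	SW	micro:I2G+p.G111Vfs*21	micro:I2G		I2G, p.G111Vfs*21	I2G	I2G, p.G111Vfs*21	I2G	A
41	M	3.66	SV	micro:p.I173N	novel:c.292+1G>A		p.I173N	c.292 + 1G > A	p.I173N	c.292 + 1G > A	D
42	F	0.17	SW	micro:I2G	micro:p.I173N		I2G	p.I173N	I2G	p.I173N	B
43	M	0.17	SW	micro:I2G	micro:p.R357W		I2G	p.R357W	I2G	p.R357W	A
44	F	2.42	SV	micro:p.I173N	micro:p.Q319X		p.I173N	p.Q319X	p.I173N	p.Q319X	B
45	F	1.17	NC	chimera:CH4	dup:E7E8[p.L308Ffs*6,p.Q319X]		UTR5, exon 1 (CH4)	p.L308Ffs*6, p.Q319X	p.P31L	p.L308Ffs*6, p.Q319X	C
46	F	3.83	NC	chimera:CH4	dup:E7E8[p.L308Ffs*6,p.Q319X]		UTR5, exon 1 (CH4)	p.L308Ffs*6, p.Q319X	p.P31L	p.L308Ffs*6, p.Q319X	C
47	M	0.03	SW	micro:p.Q319X	micro:p.R357W		p.Q319X	p.R357W	p.Q319X	p.R357W	Null
48	M	0.04	SW	micro:I2G	micro:I2G		I2G	I2G	I2G	I2G	A
49	F	6.17	SV	micro:I2G	cahx:CH1		I2G	del (CAH-X-CH1)	I2G	Exon 1-10 Del	A
50	F	0.08	SV	micro:p.I173N	micro:p.I173N		p.I173N	p.I173N	p.I173N	p.I173N	B
51	F	0.08	SW	cahx:CH1	cahx:CH1		del (CAH-X-CH1)	del (CAH-X-CH1)	Exon 1-10 Del	Exon 1-10 Del	Null
52	M	3.67	SV	micro:p.I173N	novel:p.S126X		p.I173N	p.S126X	p.I173N	p.S126X	D
53	M	0.32	SW	micro:I2G	cahx:CH1		I2G	del (CAH-X-CH1)	I2G	Exon 1-10 Del	A
54	M	0.17	SW	micro:I2G	novel:p.R484Pfs*58		I2G	p.R484Pfs*58	I2G	p.R484Pfs	A
55	F	0.01	SV	micro:p.Q319X	micro:p.R357W		p.Q319X	p.R357W	p.Q319X	p.R357W	Null
56	M	0.17	SV	micro:E6_CLUSTER	micro:p.R357W		E6cluster	p.R357W	E6cluster	p.R357W	Null
57	F	0.02	SW	micro:I2G	cahx:CH1		I2G	del (CAH-X-CH1)	I2G	Exon 1-10 Del	A
58	M	0.65	SW	micro:UTR5+p.Q319X	micro:p.R357W		UTR5, p.Q319X	p.R357W	p.Q319X	negative	Null	paternally inherited p.R357W missed by the conventional assay
59	M	0.05	SW	chimera:CH1	cahx:CH1		del (CH1)	del (CAH-X-CH1)	Exon 1-3 Del	Exon 1-10 Del	Null
60	M	4.25	SV	micro:I2G	micro:p.I173N		I2G	p.I173N	I2G	p.I173N	B
61	M	6.58	NC	micro:p.P31L	micro:E6_CLUSTER		p.P31L	E6cluster	p.P31L	E6cluster	C
62	M	0.15	NC	micro:p.P31L	cahx:CH1		p.P31L	del (CAH-X-CH1)	p.P31L	Exon 1-10 Del	C
63	M	6.67	SV	micro:I2G	micro:p.I173N		I2G	p.I173N	I2G	p.I173N	B
64	M	0.12	SW	micro:I2G	micro:p.Q319X		I2G	Q319X	I2G	p.Q319X	A
65	F	7.33	SV	micro:I2G	novel:p.R484Q		I2G	R484Q	I2G	p.R484Q	D
66	M	0.23	SW	micro:I2G	novel:p.R484Pfs*58		I2G	R484Pfs*58	I2G	p.R484Pfs	A
67	F	0.17	SW	micro:I2G	micro:p.R357W		I2G	R357W	I2G	R357W	A
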