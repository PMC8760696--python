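sample_id	gene	chrom	pos	ref	alt	hgvs_c	hgvs_p	consequence	vaf_percent	sanger
S01	CALR	chr19	13054616	A	ATATGT	c.1153_1154insTATGT	p.Lys385Ilefs*46	frameshift insertion	35.2	detected
S01	CALR	chr19	13054617	A	C	c.1154A>C	p.Lys385Thr	nSNV	35.5	detected
S01	TET2	chr4	106180775	A	G	c.3583A>G	p.Ile1195Val	nSNV	49.6	detected
S02	CALR	chr19	13054618	A	ATTGTC	c.1154_1155insTTGTC	p.Lys385Asnfs*46	frameshift insertion	15.9	detected
S02	TET2	chr4	106196829	A	G	c.4538A>G	p.Glu1513Gly	nSNV	51.6	detected
S02	TET2	chr4	106164778	T	G	c.2604T>G	p.Phe868Leu	nSNV	48.7	detected
S02	TET2	chr4	106197393	T	A	c.4893T>A	p.Tyr1631*	stopgain	1.4	na
S03	JAK2	chr9	5073770	G	T	c.1849G>T	p.Val617Phe	nSNV	88.0	detected
S03	ASXL1	chr20	31024805	A	G	c.4299A>G	p.Gln1433Gln	sSNV	49.2	detected
S03	DNMT3A	chr2	25469502	G	A	c.1155G>A	p.Pro385Pro	sSNV	51.6	na
S04	JAK2	chr9	5073770	G	T	c.1849G>T	p.Val617Phe	nSNV	72.9	detected
S04	ASXL1	chr20	31022442	G	GGGGGGGGGTGGCCCGGGTGGAGGTGGCGGCGGGGCCACCGATGAGGGGGGGGGCAGAGGCAGCAGCA	c.1927_1928ins67	p.Gly646Trpfs*10	stopgain	31.3	detected
S05	JAK2	chr9	5073770	G	T	c.1849G>T	p.Val617Phe	nSNV	66.5	detected
S06	JAK2	chr9	5073770	G	T	c.1849G>T	p.Val617Phe	nSNV	19.2	detected
S06	U2AF1	chr21	44514777	A	C	c.470A>C	p.Gln157Pro	nSNV	9.8	undetected
S07	JAK2	chr9	5073770	G	T	c.1849G>T	p.Val617Phe	nSNV	12.1	undetected
S07	ABL1	chr9	133738306	A	G	c.1049A>G	p.Asn350Ser	nSNV	48.8	detected
S08	JAK2	chr9	5073770	G	T	c.1849G>T	p.Val617Phe	nSNV	53.7	detected
S08	RUNX1	chr21	36206711	G	T	c.924G>T	p.Gln308His	nSNV	49.6	detected
S08	SF3B1	chr2	198266834	A	G	c.2098A>G	p.Lys700Glu	nSNV	45.6	detected
S08	TET2	chr4	106193892	TG	T	c.3937del	p.Asp1314Metfs*48	frameshift deletion	46.3	detected
S08	TET2	chr4	106190862	A	G	c.3734A>G	p.Tyr1245Cys	nSNV	44.9	detected
S09	CALR	chr19	13054563	CAGAGGAGGACGAGGAGGACAAGGAGGACGACGAGGACAAGGACGAGGACGAG	C	c.1092_1143del	p.Leu367Thrfs*45	frameshift deletion	10.6	detected
S09	ASXL1	chr20	31022704	CA	C	c.2190del	p.Leu731Tyrfs*12	frameshift deletion	38.5	detected
S10	JAK2	chr9	5073770	G	T	c.1849G>T	p.Val617Phe	nSNV	12.2	undetected
S10	ASXL1	chr20	31021272	A	AA	c.1772dupA	p.Tyr591*	stopgain	40.8	detected
S10	TET2	chr4	106157698	C	T	c.911C>T	p.Ala304Val	nSNV	50.1	detected
S10	U2AF1	chr21	44514777	A	C	c.470A>C	p.Gln157Pro	nSNV	42.5	detected
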