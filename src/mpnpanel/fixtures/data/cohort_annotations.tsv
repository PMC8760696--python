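chrom	pos	ref	alt	region_class	maf_1000g	maf_exac	maf_esp6500	maf_gnomad	dbsnp_id	dbsnp_exact_allele_match	clinvar_assertion	cosmic_ids	cosmic_pathogenic
chr19	13054563	CAGAGGAGGACGAGGAGGACAAGGAGGACGACGAGGACAAGGACGAGGACGAG	C	exonic	.	.	.	.	.	false	pathogenic	COSM1738055	true
chr19	13054618	A	ATTGTC	exonic	.	.	.	.	rs765476509	true	absent	COSM1738056	false
chr19	13054616	A	ATATGT	exonic	.	.	.	.	.	false	absent	COSM5985669	false
chr19	13054617	A	C	exonic	.	.	.	.	rs1024435400	true	absent	.	false
chr9	5073770	G	T	exonic	.	.	.	.	rs77375493	true	pathogenic	COSM12600	true
chr9	133738306	A	G	exonic	.	.	.	.	rs144448357	true	absent	.	false
chr20	31022442	G	GGGGGGGGGTGGCCCGGGTGGAGGTGGCGGCGGGGCCACCGATGAGGGGGGGGGCAGAGGCAGCAGCA	exonic	.	.	.	.	rs750318549	false	absent	.	false
chr20	31021272	A	AA	exonic	.	.	.	.	rs762036456	true	absent	COSM4169775,COSM4169776	false
chr20	31022704	CA	C	exonic	.	.	.	.	.	false	absent	.	false
chr20	31024805	A	G	exonic	.	.	.	.	.	false	absent	.	false
chr2	25469502	G	A	exonic	.	.	.	.	rs368009374	true	VUS	.	false
chr21	36206711	G	T	exonic	.	.	.	.	rs80314254	true	benign	.	false
chr2	198266834	A	G	exonic	.	.	.	.	rs559063155	true	likely_pathogenic	COSM84677	false
chr4	106157698	C	T	exonic	.	.	.	.	.	false	absent	COSM5610834,COSM5610835	false
chr4	106164778	T	G	exonic	.	.	.	.	rs147836249	true	absent	COSM871070	false
chr4	106180775	A	G	exonic	.	.	.	.	rs568009712	true	absent	.	false
chr4	106190862	A	G	exonic	.	.	.	.	.	false	absent	.	false
chr4	106193892	TG	T	exonic	.	.	.	.	.	false	absent	COSM4383928	false
chr4	106196829	A	G	exonic	.	.	.	.	rs553669299	true	absent	.	false
chr4	106197393	T	A	exonic	.	.	.	.	.	false	absent	COSM97191	true
chr21	44514777	A	C	exonic	.	.	.	.	rs371246226	true	likely_pathogenic	COSM211534,COSM1318797	false
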