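sample_id	mpn_subtype	age_years	sex	ethnicity	hb_g_dl	wbc_1e9_l	platelet_1e9_l	hepatosplenomegaly	constitutional_symptoms	smoker
S01	ET	30	M	Malay	17.1	7.6	1730	no	no	no
S02	ET	50	F	Chinese	13.2	10.9	776	no	no	no
S03	ET	79	M	Malay	11.1	24.5	869	no	no	yes
S04	PV	54	M	Chinese	18.9	17.2	426	no	yes	yes
S05	PV	66	F	Chinese	19.3	18.1	423	no	yes	no
S06	PV	73	M	Dutch	20.0	9.0	334	no	yes	yes
S07	pre-PMF	50	M	Chinese	15.0	17.8	859	no	yes	yes
S08	pre-PMF	50	F	Malay	8.7	58.4	1099	no	yes	no
S09	overt-PMF	46	M	Malay	7.1	3.9	452	yes	no	no
S10	overt-PMF	63	M	Chinese	7.3	5.5	54	no	yes	yes
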