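# Published case series: 13 psoriasis patients who adopted a gluten-free
# diet (GfD) after inadequate response to their ongoing therapy.
# Transcribed field-for-field from the published patient table, including
# the original treatment spellings. "neg" in a titer column means the
# quantitative test was negative; ND = not determined; NI = no improvement;
# not_applicable = patient does not suffer from PsA; NR = not reported.
patient_id	sex	clinical_type	age_of_onset_y	gliadin_screen	igg_plus_iga_u_ml	iga_u_ml	age_at_gfd_y	treatment	pasi_baseline	pasi_improvement	psa_improvement	relapse_on_dietary_error
1	M	PsO	23	pos	11.1	2	43	Acitretin	15.3	NI	not_applicable	NR
2	M	PsO	7	neg	9.8	3.2	30	FAE	14	NI	not_applicable	NR
3	F	PsO	32	pos	ND	ND	64	anti-TNF	25.4	NI	not_applicable	NR
4	M	PsO,PsA	51	pos	12.5	1	55	anti IL-12/IL-23	17.6	NI	NI	NR
5	M	PsO	17	pos	10.6	8	47	Acitretin	12.2	NI	not_applicable	NR
6	M	PsO	11	pos	12.5	8.5	36	Acitretin + FAE	26	NI	not_applicable	NR
7	M	PsO	7	pos	13.5	12.1	41	Acitretin	28.5	PASI90	not_applicable	NR
8	M	PsO,PsA	9	neg	neg	neg	55	Acitretin	22	PASI90	Yes	Yes
9	M	PsO,PPPP	28	pos	17.9	17.9	73	Aprimelast	15.9	PASI75	not_applicable	Yes
10	F	PsO,PsA	27	pos	19.9	17.6	70	ADA, aIL-12/IL-23, aIL-17 disc.	8.8	PASI75	Yes	NR
11	M	PsO	26	neg	neg	neg	48	Acitretin	18.4	PASI90	not_applicable	NR
12	M	PsO	30	neg	neg	neg	73	MTX, ADA disc.	15.0	PASI90	not_applicable	NR
13	M	PsO	16	neg	neg	neg	39	Acitretin	14.7	PASI75	not_applicable	NR
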