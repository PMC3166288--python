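organism	group	accession	name	experimental	predicted
Homo sapiens	mammals	NP_001012333	Midkine	129-143	120-143
Homo sapiens	mammals	NP_055701	NSA2	10-41	133-155
Homo sapiens	mammals	NP_055701	NSA2	131-154	133-155
Homo sapiens	mammals	NP_872604	RASSF5	51-100	78-98
Homo sapiens	mammals	NP_037541	follistatin	93-116	98-121
Homo sapiens	mammals	CAA41051	histone H2B	28-35	15-42
Mus musculus	mammals	NP_001012495	Cxcl12	98-118	92-119
Mus musculus	mammals	NP_081208	NoBP	220-262	230-255;276-306
Mus musculus	mammals	NP_082355	aminopeptidase O	688-725	682-712
Dictyostelium discoideum	amoeba	XP_002649205	eIF6	31-64	27-49;295-320
Dictyostelium discoideum	amoeba	XP_002649205	eIF6	246-252	27-49;295-320
Aplysia kurodai	molluscs	B0FRH7	ApLLP	1-19	1-21;96-120
Aplysia kurodai	molluscs	B0FRH7	ApLLP	90-120	1-21;96-120
Trypanosoma brucei	trypanosomes	CAD21884	ESAG8	48-79	
Trypanosoma cruzi	trypanosomes	XP_817097	Met-III	1-19	
Trypanosoma cruzi	trypanosomes	XP_817097	Met-III	146-191	
Solanum lycopersicum	plants	Q944N1	LHP1	141-171	141-165;276-296
Arabidopsis thaliana	plants	NP_001078269	HMGB1	1-47	22-60
Bovine herpesvirus 1	viruses_mammalian_host	CAA90914	BICP27	86-97	75-108
Human adenovirus C	viruses_mammalian_host	YP_001551773	E4orf4	66-75	61-82
SARS coronavirus	viruses_mammalian_host	P59633	Non-structural protein 3b	134-154	
HTLV-1	viruses_mammalian_host	BAH85789	Tof	71-98	
Human herpes simplex virus	viruses_mammalian_host	P08353	Gamma-1 34.5 protein	1-16	1-22
Human adenovirus 2	viruses_mammalian_host	P68950	protein VII	93-112	90-117
African swine fever virus	viruses_mammalian_host	AAA87288	I14L	1-14	1-26
PRRSV	viruses_mammalian_host	AAD00244	N protein	41-48	1-21;32-59
Tomato leaf curl Java virus	viruses_plant_host	BAD90868	Capsid protein	1-30	
Potato leafroll virus	viruses_plant_host	P11624	Capsid protein	17-31	10-64
Marek's disease virus type 1	viruses_avian_host	AAS01627	MEQ protein	62-78	22-47;52-81
Avian infectious bronchitis virus	viruses_avian_host	CAC39307	N protein	71-78	347-377
Betanodavirus GGNNV	viruses_fish_host	NP_689432	Protein alpha	23-31	10-40
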