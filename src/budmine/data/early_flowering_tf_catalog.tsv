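gene_id	orthologue_id	family	preferred_name
Prupe.2G213000	Pm018533	ARF	ARF16
Prupe.2G182800	Pm018422	bZIP	GBF3
Prupe.8G126600	Pm021430	bZIP	ABF4
Prupe.2G192300	Pm018337	Dof	DAG1
Prupe.2G314800	Pm019710	Dof	DOF4.6
Prupe.5G089900	Pm023777	AP2/ERF	CBF4
Prupe.5G090600	Pm023768	AP2/ERF	ERF025
Prupe.5G117800	Pm024053	AP2/ERF	ERF061
Prupe.5G090000	Pm023773	AP2/ERF	CBF1
Prupe.5G090100	Pm023775	AP2/ERF	DREB1A
Prupe.3G019900	Pm013049	AP2/ERF	CRF4
Prupe.1G074100	Pm004420	FAR1	FAR1
Prupe.7G206900	Pm027197	HSF	HSFA6B
Prupe.7G231100	Pm027421	HSF	HSFC1
Prupe.1G531600	Pm004416	MADS-box	SVP
Prupe.1G290500	Pm030595	MADS-box	AGL4
Prupe.1G489400	Pm004718	MADS-box	PI
Prupe.2G109500	Pm017464	MADS-box	AGL80
Prupe.3G111300	Pm014563	MADS-box	AG
Prupe.1G531500	Pm004417	MADS-box	AGL24
Prupe.4G126900	Pm010927	MYB	MYB67
Prupe.3G268000	Pm015880	MYB	MYB96
Prupe.1G441700	Pm005220	MYB	MYB73
Prupe.1G413700	Pm005487	TALE	ATH1
Prupe.3G270800	Pm015851	WRKY	WRKY72
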