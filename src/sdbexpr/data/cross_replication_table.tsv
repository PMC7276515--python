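mesa_probe	fos_probeset	entrez_id	gene	discovery_cohort	trait	sign	discovery_p	discovery_q	cross_replication_p	heartbeat_p
ILMN_1708881	3525498	55647	RAB20	FOS	avgO2	+	1.22E-07	2.17E-03	0.037	0.046
ILMN_1678075	2892979	9425	CDYL	FOS	avgO2	-	6.80E-06	4.05E-02	0.044	0.229
ILMN_1702636	3779579	84617	TUBB6	MESA	minO2	-	2.02E-06	3.29E-03	0.032	0.908
ILMN_1699489	3779579	84617	TUBB6	MESA	minO2	-	1.47E-04	4.55E-02	0.032	0.908
ILMN_1717877	2448073	10625	IVNS1ABP	MESA	minO2	+	7.71E-06	9.12E-03	0.018	0.144
ILMN_2397750	2448073	10625	IVNS1ABP	MESA	minO2	+	2.64E-06	3.60E-03	0.018	0.144
ILMN_2235283	3954238	5594	MAPK1	MESA	minO2	-	1.43E-06	2.85E-03	0.037	0.830
ILMN_2058251	3236958	7431	VIM	MESA	avgO2	-	7.10E-05	4.72E-02	0.002	0.823
ILMN_1747775	3478457	2054	STX2	MESA	avgO2	+	1.39E-05	2.33E-02	0.008	0.568
ILMN_1656920	3554851	1396	CRIP1	MESA	minO2	-	7.97E-05	3.48E-02	0.037	0.198
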