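mesa_probe	fos_probeset	entrez_id	gene	trait	sign	meta_p	meta_q	heartbeat_p
ILMN_1708881	3525498	55647	RAB20	avgO2	+	1.93E-08	2.14E-04	0.046
ILMN_2381257	3802980	1824	DSC2	avgO2	-	3.26E-07	1.78E-03	0.999
ILMN_2397750	2448073	10625	IVNS1ABP	minO2	+	5.51E-07	5.56E-03	0.144
ILMN_1663119	3802980	1824	DSC2	avgO2	-	6.13E-07	2.27E-03	0.999
ILMN_2235283	3954238	5594	MAPK1	minO2	-	9.52E-07	5.56E-03	0.830
ILMN_1717877	2448073	10625	IVNS1ABP	minO2	+	1.54E-06	5.78E-03	0.144
ILMN_1702247	3591327	23582	CCNDBP1	AHI	+	1.99E-06	2.43E-02	0.944
ILMN_2046730	2435383	6281	S100A10	minO2	-	2.01E-06	5.87E-03	0.949
ILMN_1678075	2892979	9425	CDYL	avgO2	-	2.43E-06	5.44E-03	0.229
ILMN_1747775	3478457	2054	STX2	avgO2	+	4.34E-06	6.86E-03	0.568
ILMN_1796712	2435383	6281	S100A10	avgO2	-	4.86E-06	7.11E-03	0.949
ILMN_2058251	3236958	7431	VIM	avgO2	-	5.19E-06	7.25E-03	0.823
ILMN_1768110	2515933	51776	ZAK	avgO2	-	5.94E-06	7.53E-03	0.987
ILMN_2230902	2830946	1495	CTNNA1	avgO2	-	6.91E-06	7.82E-03	0.847
ILMN_1796712	2435383	6281	S100A10	minO2	-	7.35E-06	1.72E-02	0.949
ILMN_2046730	2435383	6281	S100A10	avgO2	-	7.96E-06	8.08E-03	0.949
ILMN_1765060	3536786	55030	FBXO34	avgO2	-	8.02E-06	8.09E-03	0.416
ILMN_1656920	3554851	1396	CRIP1	minO2	-	1.67E-05	3.23E-02	0.198
ILMN_1719433	2362157	912	CD1D	avgO2	+	1.85E-05	1.68E-02	0.002
ILMN_1755937	3627248	302	ANXA2	minO2	-	2.52E-05	4.21E-02	0.860
ILMN_1782538	3236958	7431	VIM	avgO2	-	3.41E-05	2.69E-02	0.823
ILMN_1717163	2940202	2162	F13A1	avgO2	-	4.85E-05	3.41E-02	0.846
ILMN_1810069	2525182	151195	CCNYL1	avgO2	-	5.38E-05	3.64E-02	0.950
ILMN_2329679	3955915	8459	TPST2	avgO2	-	6.91E-05	4.21E-02	0.122
ILMN_1769810	2628682	10550	ARL6IP5	avgO2	-	6.95E-05	4.22E-02	0.824
ILMN_1703926	3535780	5732	PTGER2	avgO2	-	7.56E-05	4.42E-02	0.516
ILMN_2366391	2410241	5052	PRDX1	avgO2	-	7.82E-05	4.50E-02	0.885
ILMN_1717877	2448073	10625	IVNS1ABP	avgO2	+	8.42E-05	4.67E-02	0.144
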