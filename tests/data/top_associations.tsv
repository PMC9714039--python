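mode	trait	marker_id	chrom	pos	maf	gene	effect_allele	other_allele	n_probands	effect	se	chi2	p_printed
general	WISC_Arithmetic	psy_rs78265488	8	2955158	0.4717	CSMD1	C	T	389	-0.199	0.036	31.12	2e-08
general	WISC_Arithmetic	rs255472	8	3842999	0.2731	CSMD1	T	C	396	-0.155	0.028	30.47	3e-08
general	WISC_Arithmetic	rs11995240	8	3848025	0.1691	CSMD1	T	C	396	-0.016	0.003	29.84	5e-08
general	WISC_Arithmetic	rs17068473	8	3854987	0.2854	CSMD1	G	T	396	0.183	0.033	30.72	3e-08
general	WISC_Arithmetic	rs4875262	8	3876265	0.3858	CSMD1	G	A	396	0.262	0.046	31.95	2e-08
general	WISC_Arithmetic	rs2740929	8	3879918	0.4877	CSMD1	C	T	396	-0.191	0.034	31.03	3e-08
general	WISC_Arithmetic	rs2740878	8	3918118	0.3288	CSMD1	A	G	396	-0.309	0.054	33.05	9e-09
general	WISC_Arithmetic	rs2552166	8	3920395	0.1734	CSMD1	G	A	396	-0.326	0.057	32.16	1e-08
general	WISC_Arithmetic	rs604900	20	2296172	0.3721	NA	C	T	398	0.132	0.024	30.56	3e-08
general	WISC_Arithmetic	rs6117457	20	733963	0.2883	NA	T	C	398	-0.359	0.062	33.9	6e-09
general	WISC_Arithmetic	psy_rs79359757	20	937853	0.07381	NA	C	T	398	-0.053	0.01	30.01	4e-08
general	WISC_Arithmetic	rs7261002	20	1002656	0.1835	NA	G	A	398	0.366	0.064	32.9	1e-08
general	WISC_Arithmetic	rs6118727	20	1030235	0.4465	NA	A	G	398	0.071	0.013	30.15	4e-08
general	WISC_Arithmetic	rs200896	20	1789409	0.4292	NA	A	C	398	-0.326	0.056	33.38	8e-09
general	WISC_Arithmetic	psy_rs200888	20	1796461	0.3931	NA	G	T	396	0.138	0.025	30.49	3e-08
general	WISC_Arithmetic	psy_rs4813309	20	1880550	0.1331	SIRPA	C	T	397	-0.444	0.078	32.7	1e-08
general	WISC_Arithmetic	psy_rs6035018	20	1882954	0.19	SIRPA	T	C	398	-0.392	0.068	33.07	9e-09
general	WISC_Arithmetic	exm1519370	20	1896100	0.3994	SIRPA	C	T	388	-0.128	0.023	30.41	4e-08
general	WISC_Arithmetic	psy_rs73069290	20	1904515	0.06936	SIRPA	G	T	398	0.068	0.012	30.03	4e-08
general	WISC_Arithmetic	rs6035139	20	1936275	0.06014	NA	G	A	398	-0.905	0.163	30.94	3e-08
general	WISC_Arithmetic	rs214831	20	2321363	0.3967	TGM3	G	A	398	-0.395	0.067	35.28	3e-09
general	WISC_Arithmetic	rs6137776	20	2338454	0.2392	NA	T	C	398	0.281	0.05	31.82	2e-08
general	WISC_Symbol_Search	rs2673776	6	152522812	0.4429	SYNE1	C	A	396	0.163	0.029	31.84	2e-08
general	WISC_Symbol_Search	exm2270431	6	152644111	0.4565	SYNE1	C	T	396	0.146	0.026	31.44	2e-08
general	WISC_Symbol_Search	psy_rs9478324	6	152677815	0.05058	SYNE1	G	A	396	0.287	0.052	30.51	3e-08
maternal	SRS	rs1451197	2	2741446	0.4993	NA	G	A	213	-4.888	0.872	31.42	2e-08
maternal	SRS	rs2176347	2	45968233	0.4473	PRKCE	T	G	231	-3.441	0.624	30.39	4e-08
maternal	SRS	rs7604835	2	152881908	0.1315	CACNB4	G	A	287	-11.482	1.927	35.51	3e-09
maternal	SRS	psy_rs77672109	4	35576468	0.01662	NA	C	A	304	-58.859	10.144	33.67	7e-09
maternal	SRS	rs11934637	4	92981939	0.0289	NA	T	G	304	-34.434	5.853	34.61	4e-09
maternal	SRS	psy_rs146416593	5	60662093	0.01592	ZSWIM6	G	A	324	-33.216	5.844	32.31	1e-08
maternal	SRS	psy_rs79166730	5	175229558	0.01951	CPLX2	G	T	321	-37.303	5.817	41.13	1e-10
maternal	SRS	exm573219	6	116325108	0.01879	FRK	G	A	325	-58.949	9.981	34.88	4e-09
maternal	SRS	psy_rs78989171	8	49645477	0.01301	EFCAB1	G	T	308	-58.867	10.204	33.28	8e-09
maternal	SRS	exm754630	9	74319677	0.01806	TMEM2	T	C	322	-26.113	4.085	40.87	2e-10
maternal	SRS	rs1681993	12	63338414	0.01084	NA	G	A	324	-58.96	10.14	33.81	6e-09
maternal	SRS	rs7956933	12	63345018	0.01085	NA	A	G	323	-58.964	10.151	33.74	6e-09
maternal	SRS	psy_rs10860381	12	99309750	0.01375	ANKS1B	G	A	305	-58.851	10.206	33.25	8e-09
maternal	WISC_Arithmetic	rs11784069	8	2119582	0.3736	NA	T	G	271	0.341	0.061	31.1	2e-08
maternal	WISC_Arithmetic	rs7261002	20	1002656	0.1835	NA	G	A	314	0.661	0.116	32.68	1e-08
maternal	WISC_Symbol_Search	rs2256135	6	152464839	0.4566	SYNE1	G	A	262	0.264	0.047	31.95	2e-08
paternal	RIST_Index	exm693219	8	28929739	0.02746	KIF13B	G	A	371	42.012	7.191	34.13	5e-09
paternal	SRS	exm1090011	1	56314440	0.01517	TSACC	T	G	320	-42.257	7.231	34.15	5e-09
paternal	SRS	psy_rs191695175	8	122841477	0.01016	NA	T	C	326	-47.854	5.665	71.36	3e-17
paternal	SRS	rs16908233	11	21604897	0.01158	NA	A	G	317	-34.271	5.86	34.2	5e-09
paternal	SRS	psy_rs117476444	13	113442872	0.02168	ATP11A	G	A	320	-33.185	5.847	32.21	1e-08
paternal	WISC_Arithmetic	rs11784069	8	2119582	0.3736	NA	T	G	271	-0.273	0.049	30.71	3e-08
paternal	WISC_Arithmetic	rs2740939	8	3872513	0.4899	CSMD1	C	A	253	-0.244	0.044	30.73	3e-08
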