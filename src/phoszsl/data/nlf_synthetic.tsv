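residue	d1	d2	d3	d4	d5	d6	d7	d8	d9	d10	d11	d12	d13	d14	d15	d16	d17	d18
A	0.0215	0.9144	0.7036	0.0663	0.0966	0.1005	0.6857	0.5924	1.0194	0.4480	0.2737	0.3559	0.1234	0.5441	0.0843	0.3045	0.6800	0.1975
C	-1.1070	1.1120	1.7140	-0.6790	1.8386	-0.9592	-0.7338	0.3237	-0.2975	-0.1885	-0.1191	-0.1721	-0.0693	-0.1191	-0.1855	-0.0638	-0.0604	-0.0400
D	1.5208	-0.0045	0.3117	-0.5316	-0.9866	-0.0878	-1.6109	0.4236	-0.2989	-0.3391	-0.3258	0.3916	-0.2194	-0.0196	0.7242	0.0511	0.1994	0.0759
E	1.4212	-0.2310	-0.6095	0.3390	-0.3115	-0.1401	-1.0030	0.6534	0.5094	0.3934	-0.0697	0.1339	0.2175	0.0506	-0.8297	-0.2391	-0.0219	-0.5398
F	-1.6650	-1.0089	-0.2104	-0.6350	-0.5667	0.2320	-0.0155	0.2550	0.4800	-1.2985	0.2705	0.4487	-0.1900	-0.2632	-0.5409	0.1827	-0.0439	0.3632
G	0.8415	-0.1722	1.7259	-0.0603	-0.6939	1.1377	1.1932	0.8510	-0.4393	0.1258	-0.2069	-0.1883	-0.2986	-0.3914	-0.0475	-0.3485	-0.1698	-0.0880
H	0.6560	-1.5502	-0.6724	-1.5464	0.4987	-0.7131	0.6643	-0.0987	-0.3168	0.9702	-0.0395	0.6668	0.3408	-0.3158	0.0524	-0.0760	-0.0524	0.1867
I	-1.5067	1.1234	-0.7157	-0.4241	-0.5668	0.2626	-0.1417	0.0664	-0.1889	0.2687	-0.5652	-0.0139	0.1097	0.3130	0.1001	0.2700	-0.5427	0.0813
K	1.0765	0.0371	-0.7154	0.8795	0.7855	0.1618	0.1996	0.1265	0.3551	-0.7269	-0.6424	-0.4119	0.9139	-0.4977	0.2258	-0.1646	0.1276	0.2693
L	-1.4560	0.8531	-0.8060	0.1615	0.0298	0.3726	0.0927	-0.0494	-0.4431	-0.1161	0.1189	0.3346	0.0986	0.5359	0.0881	-1.0459	0.1010	0.0784
M	-1.0353	0.5811	-0.8160	0.5481	0.1599	0.3499	0.0595	0.0919	-0.9892	-0.0424	0.9161	0.2034	0.0603	-0.5841	0.1522	0.3555	0.3639	-0.4561
N	1.4594	-0.2161	0.0823	-0.9767	0.0781	0.8431	-0.0533	-1.0060	-0.8656	-0.2890	-0.0467	-0.5984	0.1580	0.5335	-0.4352	0.2448	0.3307	0.0680
P	0.8668	0.6761	0.2503	0.7809	-1.1367	-2.1344	0.9146	-0.3643	-0.4438	-0.4481	0.0246	-0.0060	-0.0271	0.1351	-0.1277	0.0290	-0.0522	-0.0060
Q	1.0241	-0.2985	-0.7361	0.7473	0.4348	-0.1022	-0.4312	0.4384	-0.0851	0.4807	0.9340	-0.6106	-0.6347	0.0320	-0.0172	-0.0378	-0.2314	0.6132
R	0.9616	-0.1915	-0.7841	0.6502	1.2870	0.3486	0.6269	-0.0386	0.0690	-0.3730	-0.6717	0.5362	-0.7978	0.3116	0.1095	0.3264	-0.2190	-0.2734
S	0.7789	0.4456	0.6492	-0.2348	0.0175	0.4150	0.0397	-0.3688	0.5801	-0.2003	0.9715	0.0900	0.6805	0.1966	0.3085	0.1595	-0.6577	-0.2149
T	0.1256	0.7308	0.3770	0.0750	-0.1557	0.2244	-0.2619	-1.7064	0.8610	0.3166	-0.0250	0.1553	-0.5402	-0.5612	0.0026	-0.3045	0.1016	-0.0063
V	-1.1795	1.2240	-0.5543	-0.0904	-0.6159	0.0950	0.0235	0.1364	0.1662	0.7281	-0.5932	-0.5310	0.0397	-0.3095	-0.1196	0.3623	0.0192	0.0780
W	-1.5980	-2.2816	1.2191	1.6703	-0.0878	0.1252	-0.5221	-0.4436	-0.3080	0.4846	-0.2686	0.1773	0.3048	0.2210	0.0127	0.1564	-0.0151	0.0802
Y	-1.2063	-1.7432	-0.4131	-0.7398	-0.1049	-0.5315	0.2736	0.1170	0.6361	-0.1943	0.0643	-0.9614	-0.2702	0.1882	0.4430	-0.1618	0.1432	-0.4671
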