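drug	compound_id	targets	random	dir	ind	cs	max_de	mean_de	lr	rf
vinorelbine	K10916986	TUBB6,TUBA1A,TUBB2A,TUBB2C	310	126	128	1318	1690	425	28	88
dexamethasone	A69951442	NR3C1	1498	1891	284	943	315	1143	757	157
dasatinib	K49328571	LCK,YES1	2325	1009	94	222	290	2621	182	532
vincristine	A76528577	TUBB6,TUBA1A,TUBB2A,TUBB2C	1979	473	439	386	2231	2196	456	37
mycophenolate-mofetil	K92428153	IMPDH2	564	1100	1263	2986	100	301	3064	3086
amlodipine	A22032524	CACNA1D	995	1338	2439	1801	1875	974	3037	650
lovastatin	A70155556	HMGCR	1712	72	811	2078	1124	1068	1334	55
clobetasol	A26095496	NR3C1	2194	820	21	157	74	15	38	65
calcitriol	K27316855	VDR	2514	1059	2938	221	125	1814	1299	252
flutamide	K28307902	AR	919	2604	69	2806	463	298	702	647
prednisolone	A27887842	NR3C1	2382	1439	206	787	402	1068	257	23
nifedipine	K96354014	CACNA1D	940	1225	1465	1285	88	322	3037	2249
vemurafenib	K56343971	BRAF	1042	1	82	1	1149	1403	22	2
glibenclamide	K36927236	KCNJ11	29	1415	2028	409	1059	740	1300	366
digoxin	A94756469	ATP1A3,FXYD2,ATP1B1	2376	73	1470	118	828	567	732	44
bortezomib	K88510285	PSMB10,PSMA3,PSMA1,PSMA5,PSMB7,PSMB5,PSMA8,PSMB1	1882	1	1	2	2546	2513	24	5
vinblastine	A22783572	TUBB6,TUBA1A,TUBB2A,TUBB2C	1612	515	56	100	224	377	38	2
digitoxin	A93236127	ATP1A3,FXYD2,ATP1B1	573	89	430	216	521	653	79	50
losartan	K76205745	AGTR1	645	489	988	770	636	31	735	1931
pitavastatin	K30097969	HMGCR	1855	1976	1036	1117	90	527	1632	373
digoxin	A75144621	ATP1A3,FXYD2,ATP1B1	69	521	776	194	127	559	208	64
hydrocortisone	A65767837	NR3C1	303	312	72	58	93	122	29	17
paclitaxel	A28746609	TUBB6,TUBA1A,TUBB2A,TUBB2C	2299	74	121	47	371	1862	79	19
lovastatin	K09416995	HMGCR	988	1	735	1587	1698	1484	128	100
irinotecan	K08547377	TOP1	1742	1023	20	236	128	1886	46	160
vincristine	A60414806	TUBB6,TUBA1A,TUBB2A,TUBB2C	1394	96	74	17	1272	69	28	9
vinblastine	A55594068	TUBB6,TUBA1A,TUBB2A,TUBB2C	1359	490	75	1383	373	1735	35	2
raloxifene	K63828191	ESR2	2080	2883	1818	1172	1064	479	1114	2520
digoxin	K23478508	ATP1A3,FXYD2,ATP1B1	1005	102	1066	112	2096	2027	252	167
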