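gene	chromosome	position	maf	beta_dbp	ve_dbp_pct	beta_sbp	ve_sbp_pct
MAP4	3	48040283	0.0318	-6.22	2.29	-9.91	2.78
LEPR	1	66075952	0.1567	2.76	2.19	3.87	2.06
MAP4	3	47957996	0.0301	-4.64	1.22	-7.39	1.49
MAP4	3	47956424	0.3777	-1.50	1.17	-2.38	1.43
MAP4	3	48040284	0.0131	-6.95	0.91	-11.07	1.11
FLT3	13	28624294	0.4167	1.38	1.01	1.79	0.81
MAP4	3	47913455	0.0049	-5.46	0.36	-8.70	0.44
RAI1	17	17696755	0.4870	0.75	0.30	0.50	0.06
MAP4	3	47957741	0.0016	-5.09	0.24	-8.10	0.30
FLNB	3	58109162	0.4947	0.39	0.08	1.00	0.27
ZNF443	19	12541795	0.3624	-0.65	0.26	-0.77	0.17
CABP2	11	67288594	0.3911	0.62	0.21	0.80	0.17
ZNF544	19	58772579	0.2150	-0.71	0.18	-0.54	0.05
LRP8	1	53712727	0.2117	0.00	0.00	-0.99	0.17
EPS8L1	19	55598724	0.4456	0.50	0.14	0.55	0.08
FLT3	13	28601297	0.0016	3.24	0.11	4.21	0.09
MTRR	5	7897191	0.3660	-0.44	0.10	0.00	0.00
ZNF17	19	57931303	0.2993	-0.47	0.10	-0.37	0.03
HIF3A	19	46812451	0.0369	0.99	0.09	0.95	0.04
ZNF180	19	44983567	0.3417	-0.40	0.08	-0.46	0.05
GAB2	11	77937768	0.0082	0.00	0.00	3.09	0.08
SIX5	19	46269076	0.3784	0.38	0.08	0.00	0.00
TCIRG1	11	67809268	0.0369	1.07	0.08	1.38	0.06
MTRR	5	7889304	0.1248	-0.50	0.07	0.00	0.00
MTRR	5	7870973	0.2305	-0.38	0.06	0.00	0.00
MTRR	5	7891506	0.1230	-0.46	0.06	0.00	0.00
NEXN	1	78392446	0.1298	-0.48	0.06	0.00	0.00
P2RY2	11	72946204	0.0985	-0.45	0.04	-0.59	0.03
COL5A3	19	10085054	0.1448	0.32	0.03	0.54	0.04
SAT2	17	7529902	0.0434	0.34	0.01	1.11	0.04
COL5A3	19	10085062	0.1349	0.35	0.03	0.59	0.04
CAPN12	19	39228244	0.1054	0.30	0.02	0.56	0.03
ZNF443	19	12541250	0.0305	-0.58	0.03	-0.69	0.02
RHOD	11	66834232	0.0083	-0.95	0.03	0.00	0.00
RCN3	19	50045878	0.0417	0.52	0.02	0.96	0.03
ZNF177	19	9490760	0.0217	-0.74	0.03	-0.69	0.01
ZNF443	19	12541547	0.4150	-0.20	0.02	-0.23	0.02
SPTBN4	19	41056229	0.0327	-0.59	0.01	-1.11	0.02
DNASE1L3	3	58183636	0.0456	0.36	0.01	0.67	0.02
EPHA2	1	16456763	0.0180	0.94	0.02	1.24	0.02
CYP1A2	15	75047412	0.0017	0.93	0.02	0.00	0.00
P2RX5	17	3599205	0.0170	0.59	0.02	0.00	0.00
EMP3	19	48833608	0.0306	0.00	0.00	-0.65	0.02
CCL24	7	75442723	0.0148	-0.66	0.01	-1.12	0.02
CAPN12	19	39230852	0.0349	0.41	0.01	0.77	0.02
C1QBP	17	5338281	0.0098	0.78	0.01	1.38	0.02
KRT23	17	39092756	0.1707	0.00	0.00	-0.31	0.01
RHOD	11	66837996	0.0065	-0.84	0.01	0.00	0.00
FPR1	19	52249211	0.1419	-0.22	0.01	-0.28	0.01
C9ORF72	9	27561628	0.0554	0.35	0.01	0.00	0.00
TCIRG1	11	67814983	0.0033	0.83	0.01	1.07	0.01
SNAPC3	9	15459821	0.0264	-0.46	0.01	-0.60	0.01
RAI1	17	17700053	0.0033	0.67	0.01	0.45	<0.01
BTD	3	15686693	0.0213	-0.63	0.01	-0.56	<0.01
SUMF1	3	4508742	0.1856	0.17	0.01	0.22	0.01
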