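Coordinate	Ref	SNP_Indels	Rate	Gene
4409	A	G	0.1	matK~chlB
4473	C	T	0.03	matK~chlB
4609	C	T	0.04	matK~chlB
4910	G	T	0.09	matK~chlB
5514	G	A	0.27	matK~chlB
5690	G	A	0.12	matK~chlB
9984	A	C	0.23	trnG-GCC
10349	A	C	0.06	trnG-GCC
11437	G	A	0.1	atpA
19229	G	A	0.24	rpoC2
20388	C	T	0.03	rpoC2
22162	A	T	0.15	rpoC1
23394	T	G	0.1	rpoC1
24094	C	T	0.04	rpoB
24666	G	A	0.04	rpoB
26193	C	A	0.12	rpoB
29448	T	G	0.11	psbM~trnD-GCA
29449	T	G	0.09	psbM~trnD-GCA
30550	G	T	0.07	trnE-UUC~clpP
34091	T	G	0.1	psaJ~trnP-UGG
37238	T	A	0.24	psbJ~petA
37239	T	A	0.24	psbJ~petA
37240	T	A	0.24	psbJ~petA
37263	A	-ATCT	0	psbJ~petA
38094	C	-GAAG	0	psbJ~petA
39801	A	G	0.18	petA
41670	C	T	0.1	psaI~accD
41678	C	G	0.06	psaI~accD
50842	C	T	0.06	trnH-GUG~trnT-GGU
58344	C	A	0.04	petD
64071	T	C	0.04	rpl22
65304	C	A	0.15	rpl2
70068	T	G	0.04	trnT-UGU~rps4
71282	A	C	0.04	trnS-GGA~ycf3
71422	C	G	0.12	trnS-GGA~ycf3
74477	T	G	0.23	ycf3~psaA
74535	A	C	0.05	ycf3~psaA
75726	C	T	0.04	psaA
76044	A	G	0.04	psaA
81006	T	G	0.04	trnfM-CAU~psbZ
83527	G	T	0.09	psbD~trnT-GGU
84756	A	G	0.05	tRNA-Thr~rrn16
97585	T	G	0.08	ycf1
98169	T	A	0.05	ycf1
100294	A	C	0.26	ycf1
100387	T	G	0.35	ycf1
100523	G	T	0.02	ycf1
100598	A	C	0.13	ycf1
100730	A	G	0.02	ycf1
100732	G	T	0.02	ycf1
100910	C	-GATGGTGAA	0	ycf1
101076	T	G	0.01	ycf1
101085	T	G	0.04	ycf1
101103	T	G	0.11	ycf1
101112	T	G	0.07	ycf1
101121	T	G	0.1	ycf1
101130	T	G	0.06	ycf1
101139	G	T	0.4	ycf1
101157	T	G	0.09	ycf1
101166	T	G	0.02	ycf1
102292	A	C	0.36	ycf1~rps15
102658	C	T	0.06	rps15~psaC
103514	C	T	0.06	rps15~psaC
103620	G	T	0.18	rps15~psaC
103785	G	A	0.07	rps15~psaC
104282	G	A	0.1	rps15~psaC
104944	G	A	0.2	psaC~ccsA
105020	T	C	0.13	psaC~ccsA
105446	A	C/G	0.11/0.01	psaC~ccsA
109795	A	C	0.28	rpl32~trnV-GAC
113045	T	G	0.22	rps7~trnL-CAA
114839	T	C	0.09	ycf2
114997	A	T	0.04	ycf2
117038	T	+TCTTCC	0	ycf2
119153	G	T	0.48	ycf2
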