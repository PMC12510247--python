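Gene	rpoC1	IGS	IGS	IGS	ycf1	ycf1	ycf1	ycf1	ycf1	ycf1	ycf1	ycf1	ycf1	ycf1	ycf2
Pos	23167	23593	50842	50999	98314	101076	101085	101103	101112	101121	101130	101139	101148	101157	119153
Ref	G	C	C	G	G	T	T	T	T	T	T	G	G	T	G
013	-	-	-	-	T	-	-	-	-	-	G	-	T	-	T
023	-	A	T	A	-	-	-	G	-	-	-	T	-	-	-
024	A	A	T	A	-	-	-	-	-	-	-	T	-	-	-
026	-	A	T	-	-	-	-	G	-	-	-	T	-	-	-
222aA	A	A	T	-	-	-	-	-	-	G	-	-	T	-	-
243	-	-	-	-	-	-	-	G	-	-	-	-	-	-	T
248	-	-	-	-	-	-	-	-	-	-	-	-	T	-	-
252	-	-	-	-	T	-	-	-	-	-	-	-	-	-	T
257	-	-	-	-	N	-	-	-	-	-	-	T	-	-	T
259	-	A	T	A	T	-	-	G	-	-	-	T	-	-	-
262	-	-	-	-	T	-	-	-	-	-	-	T	-	G	T
N3	-	-	-	-	-	-	-	-	-	-	-	T	-	-	-
G01	-	N	T	A	-	-	-	G	-	-	-	T	-	-	-
G10	-	-	-	-	-	-	-	G	-	-	-	-	-	-	T
G9	-	-	-	-	-	-	-	G	-	-	-	-	-	-	T
P012	-	-	-	-	T	G	G	G	G	-	G	-	-	-	T
P034	-	-	-	-	-	-	-	-	-	G	-	T	-	-	-
P043	-	-	-	-	-	-	-	-	-	-	-	-	-	G	T
P052	A	A	T	A	-	-	-	-	-	G	-	T	-	-	-
P054	-	-	-	-	-	-	-	-	-	-	-	-	-	G	T
P063	-	-	-	-	-	-	-	G	-	-	G	-	-	-	-
P064	-	-	-	-	-	-	-	-	-	-	-	-	-	G	T
Q16	-	-	-	-	-	-	-	-	-	G	-	-	-	-	T
Q26	-	-	-	-	-	-	-	-	-	-	G	-	-	-	T
Q6	-	-	-	-	T	-	-	-	-	-	-	-	-	-	T
S11	A	A	T	A	-	-	-	G	-	G	-	T	-	-	-
S3	-	-	-	-	-	-	-	-	-	-	G	-	-	-	-
S6	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-
W05	-	-	-	-	T	-	-	-	-	-	-	T	T	-	T
W11	-	-	-	-	-	-	-	-	-	-	-	T	-	-	-
W13	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
W16	A	A	T	A	-	-	-	-	-	-	-	-	-	-	-
W28	-	-	-	-	-	-	-	-	-	-	-	-	-	-	T
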