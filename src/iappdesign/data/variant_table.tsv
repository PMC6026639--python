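position	ref_residue	substitutes	n_variants	total_count
1	K	R,E,I	3	10
2	C	.	0	0
3	N	G,D	2	15
4	T	I,M	2	6
5	A	V,I,P	3	7
6	T	I	1	1
7	C	Y	1	1
8	A	V,S,E,T	4	168
9	T	M,I	2	12
10	Q	H	1	5
11	R	E,W,H	3	5
12	L	.	0	0
13	A	T,V,S	3	16
14	N	D,T,H	3	153
15	F	Y	1	1
16	L	.	0	0
17	V	D,G,T,A,I,S	6	34
18	H	R	1	209
19	S	T,F,A	3	4
20	S	G,N,C,R	4	28
21	N	S,G,H	3	43
22	N	S,T,I,K,G	5	66
23	F	I,L,M,R,A,V,G	7	206
24	G	R,A,S	3	4
25	A	T,D,P,V,S,I	6	52
26	I	V,A,L,M,Y	5	74
27	L	Y,I,F,S,H,X	6	166
28	S	V,A,L,P,T	5	53
29	S	P,A,T,H,L	5	211
30	T	V,P,R,N	4	5
31	N	K,D,S,V	4	32
32	V	M,L,G	3	10
33	G	S	1	1
34	S	A,P	2	4
35	N	S,A,T,Y,D,G,H,K	8	30
36	T	A,S	2	5
37	Y	H	1	3
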