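H	C	G	O	M	W	R
1	1	1	1	1	1	1
2p+	2a	2a	2a	2a	15	13
2q-	2b	2b	2b	2b	9	12
3	3	3	3	3	3	2
4	4	4	4	4	4	5
5	5	5	5	5	5	6
6	6	6	6	6	6	4
7/21	7/21	7/21	7/21	7	2	3
8	8	8	8	8	8	8
9	9	9	9	9	14	15
10	10	10	10	10	10	9
11	11	11	11	11	11	14
12	12	12	12	12	12	11
13	13	13	13	13	16	17
14/15	14/15	14/15	14/15	14	7	7
20/22	20/22	20/22	20/22	15	13	10
16	16	16	16	16	20	20
17	17	17	17	17	17	16
18	18	18	18	18	18	18
19	19	19	19	19	19	19
X	X	X	X	X	X	X
Y	Y	Y	Y	Y	Y	Y
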