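limb	g1	g2	g3	g4	g5	g6	g7	g8	g9	g10	g11	g12	g13	g14	g15	g16	g17	g18	g19	g20
2r	8	2	8	3	2	7	13	10	2	2	2	3	2	6	4	3	2	7	7	10
3r	7	4	9	6	3	7	15	13	1	2	2	3	3	6	5	4	3	8	9	13
4r	6	5	9	9	4	7	16	13	0	1	2	5	2	5	5	5	3	8	11	14
5r	6	6	10	8	4	7	17	14	0	1	2	5	3	5	6	6	4	10	10	14
6r	7	6	10	10	2	7	18	15	0	1	1	3	3	4	5	6	4	8	11	14
7r	7	5	10	12	2	8	18	15	0	1	2	6	3	5	6	7	4	9	12	15
8r	6	5	10	10	0	7	19	16	0	1	1	6	2	4	5	6	4	8	12	15
9r	6	5	10	11	0	8	19	16	0	1	0	7	2	5	6	6	5	9	12	15
10r	5	6	10	11	0	8	20	16	0	1	1	6	2	5	6	6	5	8	12	15
11r	6	5	9	11	1	8	19	15	0	0	2	5	2	5	6	7	5	8	12	15
12r	6	5	10	10	0	8	20	16	0	1	1	6	2	3	5	6	4	7	12	15
13r	6	5	10	11	0	8	18	15	0	1	1	6	2	4	5	7	5	7	12	16
14r	6	5	10	11	0	7	20	15	0	1	0	6	1	3	6	6	4	8	12	15
15r	6	6	10	11	0	8	18	15	0	1	0	5	2	3	4	7	5	7	10	13
16r	5	5	10	11	0	7	18	15	0	0	0	5	2	3	3	7	4	6	13	14
17r	5	5	10	11	0	7	18	14	0	0	0	5	2	4	3	7	4	6	11	14
18r	5	5	9	11	0	8	17	14	0	0	0	6	1	2	4	5	5	7	11	13
19r	5	5	9	11	0	7	17	15	0	0	0	5	2	2	3	7	4	6	10	14
20r	4	5	9	12	0	7	17	14	0	0	0	6	2	2	3	7	4	5	10	13
21r	4	5	9	10	0	7	16	14	0	0	0	6	1	2	3	6	4	5	9	12
22r	4	5	9	10	0	7	16	14	0	0	0	5	1	2	3	6	4	6	10	12
23r	4	5	9	10	0	7	16	14	0	0	0	5	1	2	3	6	4	6	10	12
24r	4	5	9	10	0	7	16	14	0	0	0	6	1	3	3	7	4	5	10	12
25r	3	4	8	10	0	7	17	14	0	0	0	5	1	2	3	6	4	4	9	13
26r	4	4	8	9	0	7	16	14	0	0	0	5	1	2	2	6	4	4	9	11
27r	3	4	8	11	0	5	16	13	0	0	0	5	1	2	2	6	4	4	9	11
28r	3	4	7	9	0	6	15	13	0	0	0	5	0	1	2	6	4	4	8	11
29r	3	4	7	9	0	6	13	13	0	0	0	5	0	1	2	6	4	3	7	10
30r	2	3	6	8	0	6	13	12	0	0	0	5	0	1	1	6	3	3	7	10
31r	2	2	6	10	0	5	12	12	0	0	0	4	0	1	1	6	3	2	8	9
32r	2	2	6	8	0	5	13	11	0	0	0	3	0	0	1	5	3	2	8	9
33r	2	2	5	8	0	3	11	11	0	0	0	3	0	0	1	5	3	2	6	9
34r	1	0	4	7	0	5	10	11	0	0	0	1	0	0	1	4	0	0	7	7
35r	1	0	3	5	0	4	9	10	(-)	(-)	0	1	0	0	1	3	1?	0	7	7
36r	1	0	2	3	0	2	8	9	0	0	0	1	0	0	1	1	0	0	5	4
36l	1	0	1	0	0	1	5	6	0	0	0	1	0	0	1	0	0	0	2	3
37r	0	0	2	2	0	1	7	6	0	0	0	1	0	0	1	0	0	0	3	3
38r	0	0	1	0	0	1	3	4	0	0	0	1	0	0	0	0	0	0	1	2
39l	(-)	(-)	(-)	(-)	(-)	(-)	(-)	1?	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	0?
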