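limb	g1	g2	g3	g4	g5	g6	g7	g8	g9	g10	g11	g12	g13	g14	g15	g16	g17	g18	g19	g20
2r	2	1	2	1	0	1	3	3	0	1	0	1	0	1	1	0	0	1	1	3
2l	2	1	2	1	0	1	4	3	0	1	0	1	0	1	1	0	0	1	2	3
3r	2	1	2	1	0	1	4	3	0	1	0	1	1	1	1	0	1	1	2	4
4r	2	1	2	2	0	1	4	4	0	1	0	1	0	1	1	1	1	2	2	4
5r	2	1	2	2	0	1	5	4	0	1	0	1	1	1	1	0	1	2	2	4
6r	2	0	2	2	0	2	5	4	0	1	0	1	1	1	1	1	1	2	3	4
7r	2	0	2	2	0	2	5	5	0	1	0	1	0	1	1	0	1	2	3	4
8r	2	0	2	2	0	2	5	5	0	1	0	1	0	1	1	0	1	2	3	4
9r	1	1	2	2	0	2	5	4	0	1	0	0	0	1	1	0	1	2	3	4
10r	1	0	2	2	0	2	4	4	0	1	0	1	0	1	1	0	1	2	3	4
11r	1	0	2	1	0	2	4	4	0	1	0	1	0	1	1	0	1	2	2	4
12r	1	0	2	2	0	1	4	4	0	1	0	1	0	1	1	0	1	2	2	4
13r	1	0	2	1	0	1	4	3	0	0	0	1	0	1	1	0	0	2	2	4
14r	1	0	2	1	0	1	4	3	0	0	0	1	0	1	1	0	0	1	2	3
15r	1	0	2	1	0	1	3	3	0	0	0	1	0	1	1	0	0	1	2	3
16r	1	0	2	1	0	1	3	3	0	0	0	0	0	1	0	0	0	1	1	3
17r	1	0	1	1	0	1	3	2	0	0	0	0	0	1	0	0	0	1	2	3
18l	1	0	1	0	0	1	3	2	0	0	0	0	0	1	0	0	0	1	1	2
19r	1	0	1	0	0	1	2	2	0	0	0	0	0	1	0	0	0	1	1	2
20r	1	0	1	0	0	0	2	2	0	0	0	0	0	0	(-)	(-)	(-)	(-)	1	2
21r	(-)	(-)	(-)	(-)	(-)	(-)	1	1	0	0	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	1	1
22l	(-)	(-)	(-)	(-)	(-)	(-)	0	1?	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	0	0
23l	(-)	(-)	(-)	(-)	(-)	(-)	(-)	1?	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	(-)	0?
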