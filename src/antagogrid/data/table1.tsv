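id	label	ai
1	CH95a	38
2	CH21	37
3	CH90	35
4	CH150a	35
5	CH156	34
6	CH43	31
7	CH22	29
8	CH144a	28
9	CH144b	28
10	CH145	28
11	CH109a	25
12	CH154a	13
13	CH37	9
14	CH113a	9
15	CH148	9
16	CH112b	7
17	CH448b	7
18	CH23	7
19	CH20b	6
20	CH450	5
21	CH30	5
22	CH41b	4
23	CH449b	3
24	CH24	2
25	CH19b	2
26	CH164b	1
27	CH38c	1
28	CH452b	1
29	CH159b	1
30	CH39a	0
31	CH448a	0
32	CH452a	0
33	CH99B	0
34	CH88	0
35	CH112a	0
36	CH29	-1
37	CH93	-1
38	CH26b	-2
39	CH160c	-3
40	CH87b	-3
41	CH25	-4
42	CH140a	-4
43	CH111	-4
44	CH157b	-5
45	CH45	-6
46	CH36	-7
47	CH449a1	-7
48	CH160a	-8
49	CH451b	-8
50	CH91b	-8
51	CH81a	-8
52	CH142	-8
53	CH44	-9
54	CH26a	-10
55	CH19a	-10
56	CH149a	-10
57	CH155a	-10
58	CH28	-11
59	CH135a	-11
60	CH98b	-11
61	CH84	-11
62	CH33	-11
63	CH447	-12
64	CH161d	-13
65	CH138	-13
66	CH158b	-13
67	CH145b	-14
68	CH159a	-14
69	CH449a2	-14
70	CH20a	-14
71	CH162	-15
72	CH446	-16
73	CH40	-16
74	CH445	-16
75	CH451a	-17
76	CH163b	-17
77	CH153a	-19
78	CH34	-26
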