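no	compound	label_observed	label_gep	label_mlp
1	N-Acetoxy-4-biphenylacetamide	0	0	0
2	N-Acetoxy-2-fluorenylacetamide	0	0	0
3	N-Acetoxy-4-phenanthrylacetamide	0	0	0
4	N-Acetoxy-N-(4-stilbenyl)acetamide	0	0	0
5	3-Amino-s-triazole	1	1	1
6	1-Anthramine	0	0	0
7	9-Anthramine	0	0	0
8	2-Anthranilacetamide	0	0	0
9	Benzidine	1	0	1
10	N-(Benzoyloxy)-fluorenylacetamide	0	1	0
11	4-Biphenyldimethylamine	0	0	0
12	3,6-Bis(dimethylamino)acridine	1	0	1
13	2-Chloro-4-phenylaniline	0	1	0
14	4′-Chloro-4-stilbenyl-N,N-dimethylamine	0	0	0
15	2-Cyano-4-stilbenamine	1	0	0
16	4,6-Diamino-2-(5-nitro-2-furyl)-s-triazine	0	1	1
17	0,0′-Dianisidine	0	0	0
18	3-Dibenzofuranylacetamide	0	0	0
19	3-Dibenzothiophenylacetamide	0	0	0
20	2,2′-Dichloro-4,4′-diaminostilbene	1	0	1
21	3,3′-Dichloro-4,4′-diaminostilbene	0	1	0
22	9,10-Dihydro-2-phenanthramine	0	0	0
23	3,3′-Dihydroxybenzidine	0	0	0
24	2-(4-(N,N-Dimethylamino)styryl) quinoline	0	0	0
25	3,2′-Dimethyl-4-biphenylamine	0	0	0
26	3,3′-Dimethyl-4-biphenylamine	0	0	0
27	2-Fluorenylacetamide	1	0	0
28	3-Fluorenylacetamide	0	0	0
29	1-Fluorenylaceto hydroxamic acid	0	0	0
30	2-Fluorenylaceto hydroxanic acid	1	0	0
31	N-Fluorenyl-2-benzamide	0	1	0
32	N-Fluorenyl-2-benzohydroxamic acid	0	0	0
33	2-Fluorenyldiacetamide	1	0	1
34	2-Fluorenyldimethylamine	1	1	1
35	2,5-Fluorenylenediacetamide	0	0	0
36	2-Fluorenylhydroxylamine	0	0	0
37	N-(2-Fluorenyl)-2,2,2-trifluoroacetamide	1	0	1
38	4′-Fluoro-4-biphenylamine	1	0	1
39	1-Fluoro-2-fluorenylacetamide	0	0	1
40	3-Fluoro-2-fluorenylacetamide	1	0	0
41	4-Fluoro-2-fluorenylacetamide	0	0	0
42	5-Fluoro-2-fluorenylacetamide	0	1	0
43	6-Fluoro-2-fluorenylacetamide	1	0	0
44	7-Fluoro-2-fluorenylacetamide	1	0	0
45	7-Fluoro-2-N-fluorenylacetohydroxamic acid	1	1	0
46	4′-Fluoro-p-phenylaniline	0	1	0
47	4′-Fluoro-4-stilbenamine	1	1	0
48	4′-Fluoro-4-stilbenyl-N,N-dimethylamine	1	0	0
49	2-Hydrazino-4-phenylthiazole	0	1	0
50	N-Hydroxy-N-(4-stilbenyl) acetamide	0	1	0
51	3-Iodo-2-fluorenylacetamide	0	0	0
52	7-Iodo-2-fluroenylacetamide	0	0	0
53	2-Methoxy-3-benzofuranylamine	0	0	0
54	7-Methoxy-2-fluorenylacetamide	1	0	1
55	1-Methoxy-2-fluorenylamine	1	0	1
56	3-Methoxy-2-fluorenylamine	0	1	0
57	4-((p-Methoxyphenyl)azo)-o-anisidine	1	0	1
58	2-Methyldiacetylbenzidine	0	0	1
59	4,4′-Methylenebis(2-chloroaniline)	1	1	1
60	4′-Methyl-4-phenylacetanilide	0	0	0
61	3-Methyl-4-phenylaniline	0	1	0
62	3-Methyl-4-stilbenamine	0	0	0
63	1-Naphthylacetohydroxamic acid	0	0	0
64	2-Naphthylhydroxylamine	0	0	0
65	9-Oxo-2-fluorenylacetamide	1	0	0
66	1-Phenanthrylacetamide	0	0	0
67	2-Phenanthrylacetamide	0	1	0
68	1-Phenanthrylamine	0	0	0
69	3-Phenanthrylamine	0	0	0
70	9-Phenanthrylamine	0	0	0
71	4-(Phenylazo) acetanilide	0	0	0
72	4-(Phenylazo) aniline	0	0	0
73	4-(Phenylazo) diacetanilide	0	0	0
74	4-(Phenylazo)-N-phenylacetohydroxamic acid	0	0	0
75	4-Stilbenamine	0	0	0
76	N-(4-Stilbenyl) acetamide	0	0	0
77	4-Stilbenyl-N,N-diethylamine	0	0	0
78	4-Stilbenyl-N,N-dimethylamine	0	0	0
79	N-(4-Styrylphenyl) hydroxylamine	0	0	0
80	3,2′,4′,6′-Tetramethyl-4-biphenylamine	1	0	0
81	o,o′-Tolidine	0	1	0
82	4-(m-Tolylazo) acetanilide	0	0	0
83	4-(m-Tolylazo) aniline	0	0	0
84	2-(o-Tolylazo)-p-toluidine	1	0	1
85	2-(p-Tolylazo)-p-toluidine	0	0	0
86	4-(o-Tolylazo)-o-toluidine	1	1	0
87	4-(o-Tolylazo)-m-toluidine	0	0	0
88	4-(m-Tolylazo)-m-toluidine	0	0	0
89	4-(p-Tolylazo)-o-toluidine	0	0	0
90	4-(p-Tolylazo)-m-toluidine	0	0	0
91	N,N,2′-Trimethyl-4-stilbenamine	0	0	0
92	N,N,3′-Trimethyl-4-stilbenamine	0	0	0
93	N,N,4′-Trimethyl-4-stilbenamine	0	0	0
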