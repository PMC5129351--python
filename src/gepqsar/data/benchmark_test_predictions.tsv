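no	compound	label_observed	label_gep	label_mlp
1	2-Anthramine	0	0	0
2	4-Biphenylacetamide	0	0	0
3	4-Biphenylacetohydroxamic acid	0	1	0
4	3-Carbazolylacetamide	0	0	1
5	2,7-Diaminofluorene	0	0	1
6	4,4′-Diaminostilbene	1	1	0
7	2-Dibenzothiophenylacetamide	0	0	0
8	3,3′-Dichlorobenzidine	0	0	0
9	2-Fluorenamine	1	1	0
10	1-Fluorenylacetamide	0	0	0
11	3-Fluorenylaceto hydroxanic acid	0	0	0
12	2,7-Fluorenyldiacetamide	1	1	0
13	2-Fluorenyldiethylamine	0	0	0
14	N,2-Fluorenylformamide	0	1	0
15	2-Fluorenylmethylamine	1	0	0
16	N,2-Fluorenylsuccinamic acid	1	0	0
17	8-Fluoro-2-fluorenylacetamide	1	0	1
18	2-Fluoro-4-phenylaniline	0	0	0
19	3′-Fluoro-4-phenylaniline	0	0	0
20	3-Methoxy-4-biphenylamine	0	1	1
21	3-Methoxy-2-fluorenylacetamide	0	1	0
22	4,4′-Methylenebis(2-methylaniline)	1	0	1
23	3-Methyl-2-naphthylamine	0	0	0
24	2-Methyl-4-phenylaniline	0	0	0
25	2′-Methyl-4-phenylaniline	0	0	0
26	2-Methyl-4-stilbenamine	0	1	0
27	2-Naphthylamine	0	0	0
28	1-Naphthylhydroxylamine	0	0	0
29	9-Phenanthrylacetamide	0	0	0
30	2-Phenanthrylacetohydroxamic acid	0	0	0
31	2-Phenanthrylamine	0	1	0
32	4-(Phynylazo)-o-anisidine	1	1	0
33	1-(Phenylazo)-2-naphthylamine	0	0	0
34	4-(Phenylazo)-N-phenylhydroxylamine	0	0	0
35	3,2′,5′-Trimethyl-4-diphenylamine	1	0	1
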