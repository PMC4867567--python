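family	hgvs_c	hgvs_c_2	exon	protein_change	protein_change_2
1	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
2	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
3	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
4	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
5	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
6	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
7	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
8	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
9	c.‐29‐?_*3450+?del		1–15	Complete gene deletion – REP‐1 absent
10	c.‐29‐(57‐63kb)_49+?del		1	Deletion of exon 1 – REP‐1 absent
11	c.‐29‐(57‐63kb)_49+?del		1	Deletion of exon 1 – REP‐1 absent
12	c.‐29‐(57‐63kb)_49+?del		1	Deletion of exon 1 – REP‐1 absent
13	c.‐29‐?_49+?del		1	Deletion of exon 1 – REP‐1 absent
14	c.3G>A		1	Affects start codon – REP‐1 absent
15	c.25_28delTTTG insAGTAATAGTAA		1	p.Phe9Serfs*14
16	c.37delG		1	p.Val13*
17	c.49+1G>A		intron 1	Splice site mutation
18	c.49+3A>G		intron 1	Splice site mutation
19	c.49+3A>G		intron 1	Splice site mutation
20	c.49+3A>G		intron 1	Splice site mutation
21	c.50‐?_314+?del		2–4	Deletion of exons 2–4 – (out‐of‐frame)
22	c.116+1G>T		intron 2	p.Gly17Glufs*21
23	c.116+1G>C		intron 2	Splice site mutation
24	c.116+1G>C		intron 2	Splice site mutation
25	c.116+1G>C		intron 2	Splice site mutation
26	c.117‐?_1166+?dup		3–8	Duplication of exons 3–8 – unable to predict
27	c.117‐?_1510+?dup		3–12	Duplication of exons 3–12 – unable to predict
28	c.167dupT		3	p.Leu56Phefs*12
29	c.190‐2A>G		intron 3	Splice site mutation – p.Glu64*
30	c.225G>A		4	p.Trp75*
31	c.232C>T		4	p.Gln78*
32	c.315‐?_1166+?del		5–8	Deletion of exons 5–8 – (in‐frame) – REP‐1 absent
33	c.316C>T		5	p.Gln106*
34	c.470_473delAAAC		5	p.Gln157Leufs*10
35	c.525_526delAG		5	p.Glu177Lysfs*6
36	c.525_526delAG		5	p.Glu177Lysfs*6
37	c.525_526delAG		5	p.Glu177Lysfs*6
38	c.563_564delTG		5	p.Val188Alafs*10
39	c.564_565delGC		5	p.Pro189Ilefs*11
40	c.652_655delTCAC		5	p.Ser218Lysfs*13
41	c.653C>G		5	p.Ser218*
42	c.700A>T		5	p.Lys234*
43	c.700A>T		5	p.Lys234*
44	c.703‐?_940+?del		6–7	Deletion of exons 6–7 – p.Leu235Argfs*4
45	c.703‐?_940+?del		6–7	Deletion of exons 6–7 – p.Leu235Argfs*4
46	c.703‐?_940+?del		6–7	Deletion of exons 6–7 – p.Leu235Argfs*4
47	c.703‐?_1166+?del		6–8	Deletion of exons 6–8 – (out‐of‐frame)
48	c.715C>T		6	p.Arg239*
49	c.715C>T		6	p.Arg239*
50	c.757C>T		6	p.Arg253*
51	c.757C>T		6	p.Arg253*
52	c.757C>T		6	p.Arg253*
53	c.757C>T		6	p.Arg253*
54	c.757C>T		6	p.Arg253*
55	c.757C>T		6	p.Arg253*
56	c.757C>T		6	p.Arg253*
57	c.757C>T		6	p.Arg253*
58	c.757C>T		6	p.Arg253*
59	c.757C>T		6	p.Arg253*
60	c.799C>T		6	p.Arg267*
61	c.799C>T		6	p.Arg267*
62	c.799C>T		6	p.Arg267*
63	c.799C>T		6	p.Arg267*
64	c.799C>T		6	p.Arg267*
65	c.808C>T		6	p.Arg270*
66	c.808C>T		6	p.Arg270*
67	c.808C>T		6	p.Arg270*
68	c.817C>T		6	p.Gln273*
69	c.819G>T		6	p.Gln273His
70	c.820‐1G>C		intron 6	Splice site mutation – skips exon 7, absent REP‐1
71	c.846delT	c.881G>T	7	p.Phe282Leufs*9
72	c.877C>T		7	p.Arg293*
73	c.877C>T		7	p.Arg293*
74	c.885_886insA		7	p.Met296Asnfs*11
75	c.889A>T		7	p.Lys297*
76	c.894delT		7	p.Thr300Hisfs*25
77	c.910G>T		7	p.Glu304*
78	c.993delC		8	p.Asn332Thrfs*12
79	c.1034C>G		8	p.Ser345*
80	c.1167‐?_1413+?del		9–11	Deletion of exons 9–11 – (out‐of‐frame)
81	c.1184delG		9	p.Gly395Valfs*14
82	c.1194T>G		9	p.Tyr398*
83	c.1218C>A		9	p.Cys406*
84	c.1218C>A		9	p.Cys406*
85	c.1234G>T		9	p.Glu412*
86	c.1273C>T		10	p.Gln425*
87	c.1327_1328delAT		10	p.Met443Valfs*18
88	c.1350‐6T>G		intron 10	Skip exon 11 – p.Arg450Argfs*4
89	c.1350‐2A>C		intron 10	Splice site mutation
90	c.1350‐(14–10)delTTGT		intron 10	Small deletion affecting a splice site
91	c.1363delG		11	p.Ala455Glnfs*3
92	c.1370T>C		11	p.Leu457Pro
93	c.1511‐?_1609+?del		13	Deletion of exon 13 – (in‐frame)
94	c.1511‐1G>A		intron 12	Splice site mutation
95	c.1511‐1G>A		intron 12	Splice site mutation
96	c.1512T>A		13	p.Tyr504*
97	c.1584_1587delTGTT		13	p.Val529Hisfs*7
98	c.1603G>T		14	p.Glu535*
99	c.1624G>T		14	p.Glu542*
100	c.1624delG		14	p.Glu542Leufs*13
101	c.1649T>C		14	p.Leu550Pro
102	C.1670C>A		14	p.Ser557*
103	C.1670C>A		14	p.Ser557*
104	c.1670C>A		14	p.Ser557*
105	c.1697_1698delAT		14	p.Asn566Argfs*19
106	c.238C>T	c.1327A>G	4	p.Leu80Phe	p.Met443Val
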