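index	name	abbreviation	hemisphere
1	Precentral gyrus	PreCG	left
2	Precentral gyrus	PreCG	right
3	Superior frontal gyrus (dorsal)	SFGdor	left
4	Superior frontal gyrus (dorsal)	SFGdor	right
5	Orbitofrontal cortex (superior)	ORBsupb	left
6	Orbitofrontal cortex (superior)	ORBsupb	right
7	Middle frontal gyrus	MFG	left
8	Middle frontal gyrus	MFG	right
9	Orbitofrontal cortex (middle)	ORBmid	left
10	Orbitofrontal cortex (middle)	ORBmid	right
11	Inferior frontal gyrus (opercular)	IFGoperc	left
12	Inferior frontal gyrus (opercular)	IFGoperc	right
13	Inferior frontal gyrus (triangular)	IFGtriang	left
14	Inferior frontal gyrus (triangular)	IFGtriang	right
15	Orbitofrontal cortex (inferior)	ORBinf	left
16	Orbitofrontal cortex (inferior)	ORBinf	right
17	Rolandic operculum	ROL	left
18	Rolandic operculum	ROL	right
19	Supplementary motor area	SMA	left
20	Supplementary motor area	SMA	right
21	Olfactory	OLF	left
22	Olfactory	OLF	right
23	Superior frontal gyrus (medial)	SFGmed	left
24	Superior frontal gyrus (medial)	SFGmed	right
25	Orbitofrontal cortex (medial)	ORBmed	left
26	Orbitofrontal cortex (medial)	ORBmed	right
27	Rectus gyrus	REC	left
28	Rectus gyrus	REC	right
29	Insula	INS	left
30	Insula	INS	right
31	Anterior cingulate gyrus	ACG	left
32	Anterior cingulate gyrus	ACG	right
33	Middle cingulate gyrus	MCG	left
34	Middle cingulate gyrus	MCG	right
35	Posterior cingulate gyrus	PCG	left
36	Posterior cingulate gyrus	PCG	right
37	Hippocampus	HIP	left
38	Hippocampus	HIP	right
39	Parahippocampal gyrus	PHG	left
40	Parahippocampal gyrus	PHG	right
41	Amygdala	AMYG	left
42	Amygdala	AMYG	right
43	Calcarine	CAL	left
44	Calcarine	CAL	right
45	Cuneus	CUN	left
46	Cuneus	CUN	right
47	Lingual gyrus	LING	left
48	Lingual gyrus	LING	right
49	Superior occipital gyrus	SOG	left
50	Superior occipital gyrus	SOG	right
51	Middle occipital gyrus	MOG	left
52	Middle occipital gyrus	MOG	right
53	Inferior occipital gyrus	IOG	left
54	Inferior occipital gyrus	IOG	right
55	Fusiform gyrus	FFG	left
56	Fusiform gyrus	FFG	right
57	Postcentral gyrus	PoCG	left
58	Postcentral gyrus	PoCG	right
59	Superior parietal gyrus	SPG	left
60	Superior parietal gyrus	SPG	right
61	Inferior parietal lobule	IPL	left
62	Inferior parietal lobule	IPL	right
63	Supramarginal gyrus	SMG	left
64	Supramarginal gyrus	SMG	right
65	Angular gyrus	ANG	left
66	Angular gyrus	ANG	right
67	Precuneus	PCUN	left
68	Precuneus	PCUN	right
69	Paracentral lobule	PCL	left
70	Paracentral lobule	PCL	right
71	Caudate	CAU	left
72	Caudate	CAU	right
73	Putamen	PUT	left
74	Putamen	PUT	right
75	Pallidum	PAL	left
76	Pallidum	PAL	right
77	Thalamus	THA	left
78	Thalamus	THA	right
79	Heschl gyrus	HES	left
80	Heschl gyrus	HES	right
81	Superior temporal gyrus	STG	left
82	Superior temporal gyrus	STG	right
83	Temporal pole (superior)	TPOsup	left
84	Temporal pole (superior)	TPOsup	right
85	Middle temporal gyrus	MTG	left
86	Middle temporal gyrus	MTG	right
87	Temporal pole (middle)	TPOmid	left
88	Temporal pole (middle)	TPOmid	right
89	Inferior temporal	ITG	left
90	Inferior temporal	ITG	right
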