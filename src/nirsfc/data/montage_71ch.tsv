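channel_id	x	y	z	roi	anatomic_label
1	-46.4	47.9	-4.7	LPF	Inferior frontal gyrus
2	-51.7	40.4	10.6	LPF	Superior frontal gyrus (dorsal) left
3	-40.9	55.7	3.2	LPF	Inferior frontal gyrus
4	-43.2	48.6	18.7	LPF	Superior frontal gyrus (dorsal) left
5	-31.4	61.2	4.9	LPF	Middle frontal gyrus left
6	-35.4	49.7	27.7	LPF	Middle frontal gyrus left
7	-17.1	66.1	6.9	LPF	Middle frontal gyrus left
8	-21.2	54.6	29.8	LPF	Middle frontal gyrus left
9	-4.6	66.1	8.7	LPF	Superior frontal gyrus (medial)
10	-5.4	54.4	34.9	LPF	Superior frontal gyrus (medial)
11	9.6	66.1	8.7	RPF	Superior frontal gyrus (medial)
12	8.8	54.3	35.0	RPF	Superior frontal gyrus (medial)
13	21.0	66.3	6.7	RPF	Middle frontal gyrus right
14	24.5	54.4	30.3	RPF	Middle frontal gyrus right
15	34.4	61.4	4.5	RPF	Middle frontal gyrus right
16	37.8	49.4	28.1	RPF	Middle frontal gyrus right
17	43.3	55.8	3.3	RPF	Superior frontal gyrus (dorsal) right
18	45.5	48.1	19.3	RPF	Inferior frontal gyrus
19	48.8	47.9	-4.3	RPF	Superior frontal gyrus (dorsal) right
20	51.0	40.1	11.7	RPF	Inferior frontal gyrus
21	-65.9	-7.1	-13.7	LT	Middle temporal gyrus left
22	-69.2	-30.7	-9.4	LT	Middle temporal gyrus left
23	-61.4	8.4	2.4	LT	Temporal pole (superior) left
24	-68.5	-17.3	7.5	LT	Middle temporal gyrus left
25	-66.8	-43.7	11.2	LT	Middle temporal gyrus left
26	-64.0	-1.9	23.7	LT	Temporal pole (superior) left
27	-66.1	-30.4	28.1	LT	Heschl gyrus left
28	-54.7	14.6	33.0	LT	Superior temporal gyrus left
29	-60.7	-16.3	40.5	LT	Inferior frontal gyrus (opercular)
30	-59.7	-44.4	42.1	LIP	Angular gyrus left
31	-51.4	0.1	49.9	P	Middle frontal gyrus left
32	-54.3	-30.3	54.5	P	Inferior parietal left
33	-46.4	47.9	-4.7	P	Middle frontal gyrus left
34	-51.7	40.4	10.6	P	Middle frontal gyrus right
35	-40.9	55.7	3.2	P	Superior parietal left
36	-14.2	1.2	72.9	P	Superior parietal right
37	16.0	2.4	73.1	P	Middle frontal gyrus right
38	-15.0	-30.6	77.3	P	Inferior parietal right
39	15.8	-30.3	78.0	RT	Superior temporal gyrus right
40	53.1	0.3	50.2	RT	Inferior frontal gyrus (opercular)
41	55.7	-29.9	54.1	RIP	Angular gyrus right
42	56.5	13.8	33.8	RT	Temporal pole (superior) right
43	62.3	-16.1	40.1	RT	Heschl gyrus right
44	60.6	-43.8	41.7	RT	Temporal pole (superior) right
45	65.6	-2.6	23.6	RT	Middle temporal gyrus right
46	67.1	-30.0	27.7	RT	Middle temporal gyrus right
47	63.0	7.5	3.4	RT	Middle temporal gyrus right
48	69.6	-17.2	7.7	RT	Middle temporal gyrus right
49	67.9	-43.0	11.4	LIP	Angular gyrus left
50	67.0	-7.1	-12.5	LIP	Angular gyrus left
51	70.3	-30.2	-8.6	RIP	Angular gyrus right
52	-57.3	-56.8	42.4	RIP	Angular gyrus right
53	-38.3	-57.1	63.1	LO	Cerebellum_Crus1 left
54	38.7	-56.8	63.2	LO	Cerebellum_Crus1 left
55	57.5	-56.0	43.3	LO	Inferior occipital left
56	-51.8	-78.1	0.5	LO	Middle occipital left
57	-55.6	-68.7	27.2	LO	Inferior occipital left
58	-37.4	-88.7	18.8	LO	Middle occipital left
59	-44.6	-79.4	34.7	LO	Middle occipital left
60	-45.5	-68.7	48.8	LO	Superior occipital left
61	-30.8	-88.5	34.9	LO	Middle occipital left
62	-29.6	-78.9	45.6	MO	Superior occipital (medial)
63	-24.8	-67.9	63.4	RO	Superior occipital right
64	-16.6	-87.1	37.4	RO	Middle occipital right
65	-0.5	-78.0	56.8	RO	Middle occipital right
66	24.2	-68.7	64.0	RO	Inferior occipital right
67	13.3	-87.0	36.9	RO	Middle occipital right
68	28.5	-78.3	45.8	RO	Middle occipital right
69	44.3	-68.5	48.9	RO	Cerebellum_Crus1 right
70	29.1	-88.2	34.0	RO	Inferior occipital right
71	43.5	-79.1	34.6	RO	Cerebellum_Crus1 right
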