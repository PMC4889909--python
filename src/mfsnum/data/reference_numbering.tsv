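# MFS reference numbering table: per protein, 12 TM helix spans (author numbering,
# OPM-style membrane boundaries), the anchor (x.0) residue and the printed label.
# Three rows carry a printed label letter that contradicts the anchor residue letter;
# both are preserved verbatim and flagged in the discrepancy column.
protein	pdb_id	helix	start	end	anchor_residue	anchor_letter	printed_label	discrepancy
XylE	4JA4	1	17	33	25	G	G1.0
XylE	4JA4	2	57	74	71	G	G2.0
XylE	4JA4	3	87	104	92	A	A3.0
XylE	4JA4	4	126	145	141	G	G4.0
XylE	4JA4	5	166	183	174	G	G5.0
XylE	4JA4	6	201	218	210	A	A6.0
XylE	4JA4	7	281	301	285	S	S7.0
XylE	4JA4	8	316	333	329	T	T8.0
XylE	4JA4	9	343	361	348	G	G9.0
XylE	4JA4	10	371	390	388	G	G10.0
XylE	4JA4	11	410	427	415	Q	G11.0	label_letter_mismatch
XylE	4JA4	12	443	463	456	A	G12.0	label_letter_mismatch
PepT	2XUT	1	18	39	22	A	A1.0
PepT	2XUT	2	53	75	66	G	G2.0
PepT	2XUT	3	86	105	93	L	L3.0
PepT	2XUT	4	110	129	124	G	G4.0
PepT	2XUT	5	153	172	160	G	G5.0
PepT	2XUT	6	178	195	189	F	F6.0
PepT	2XUT	7	304	324	309	T	T7.0
PepT	2XUT	8	335	352	342	A	A8.0
PepT	2XUT	9	376	393	379	G	G9.0
PepT	2XUT	10	404	424	418	G	G10.0
PepT	2XUT	11	444	464	449	S	S11.0
PepT	2XUT	12	483	500	489	A	A12.0
LacY	1PV6	1	10	35	13	G	G1.0
LacY	1PV6	2	41	64	55	F	F2.0
LacY	1PV6	3	75	96	84	L	L3.0
LacY	1PV6	4	103	128	111	G	G4.0
LacY	1PV6	5	143	163	147	G	G5.0
LacY	1PV6	6	167	187	177	A	A6.0
LacY	1PV6	7	222	248	248	Q	Q7.0
LacY	1PV6	8	257	278	266	T	T8.0
LacY	1PV6	9	289	309	296	G	G9.0
LacY	1PV6	10	312	332	332	G	G10.0
LacY	1PV6	11	352	373	366	S	S11.0
LacY	1PV6	12	380	399	390	L	L12.0
FucP	3O7Q	1	28	47	43	N	N1.0
FucP	3O7Q	2	64	86	73	G	G2.0
FucP	3O7Q	3	90	108	98	L	L3.0
FucP	3O7Q	4	119	140	132	G	G4.0
FucP	3O7Q	5	154	174	165	G	G5.0
FucP	3O7Q	6	210	229	219	V	V6.0
FucP	3O7Q	7	261	282	267	Q	Q7.0
FucP	3O7Q	8	301	319	306	V	V8.0
FucP	3O7Q	9	326	345	328	L	L9.0
FucP	3O7Q	10	348	372	372	G	G10.0
FucP	3O7Q	11	383	403	390	T	T11.0
FucP	3O7Q	12	412	430	419	A	A12.0
GLUT1	4PYP	1	14	36	27	G	G1.0
GLUT1	4PYP	2	64	91	79	G	G2.0
GLUT1	4PYP	3	94	112	103	A	A3.0
GLUT1	4PYP	4	119	140	134	G	G4.0
GLUT1	4PYP	5	157	176	167	G	G5.0
GLUT1	4PYP	6	187	206	197	A	A6.0
GLUT1	4PYP	7	275	295	283	Q	Q7.0
GLUT1	4PYP	8	306	326	315	I	I8.0
GLUT1	4PYP	9	335	354	340	G	G9.0
GLUT1	4PYP	10	366	387	382	G	G10.0
GLUT1	4PYP	11	402	426	415	N	S11.0	label_letter_mismatch
GLUT1	4PYP	12	431	449	441	L	L12.0
EmrD	2GFP	1	11	31	21	Q	Q1.0
EmrD	2GFP	2	43	64	55	T	T2.0
EmrD	2GFP	3	73	92	77	L	L3.0
EmrD	2GFP	4	97	116	109	G	G4.0
EmrD	2GFP	5	134	155	140	G	G5.0
EmrD	2GFP	6	157	175	169	L	L6.0
EmrD	2GFP	7	208	229	210	N	N7.0
EmrD	2GFP	8	237	261	246	S	S8.0
EmrD	2GFP	9	267	283	279	L	L9.0
EmrD	2GFP	10	289	306	295	G	G10.0
EmrD	2GFP	11	326	345	334	T	T11.0
EmrD	2GFP	12	357	378	374	L	L12.0
GlcP	4LDS	1	7	31	20	G	G1.0
GlcP	4LDS	2	41	64	54	G	G2.0
GlcP	4LDS	3	74	92	83	I	I3.0
GlcP	4LDS	4	95	115	106	G	G4.0
GlcP	4LDS	5	134	154	143	G	G5.0
GlcP	4LDS	6	159	178	168	V	V6.0
GlcP	4LDS	7	244	266	256	N	N7.0
GlcP	4LDS	8	275	295	287	N	N8.0
GlcP	4LDS	9	305	325	310	G	G9.0
GlcP	4LDS	10	335	355	349	G	G10.0
GlcP	4LDS	11	376	395	388	S	S11.0
GlcP	4LDS	12	400	418	408	A	A12.0
GlpT	1PW4	1	32	51	47	N	N1.0
GlpT	1PW4	2	65	84	77	G	G2.0
GlpT	1PW4	3	93	110	100	L	L3.0
GlpT	1PW4	4	121	139	131	G	G4.0
GlpT	1PW4	5	159	178	168	G	G5.0
GlpT	1PW4	6	190	208	197	A	A6.0
GlpT	1PW4	7	255	277	262	N	N7.0
GlpT	1PW4	8	292	311	306	T	T8.0
GlpT	1PW4	9	322	340	325	G	G9.0
GlpT	1PW4	10	349	369	363	G	G10.0
GlpT	1PW4	11	386	405	388	T	T11.0
GlpT	1PW4	12	416	435	431	L	L12.0
MelB	4M64	1	11	29	23	G	G1.0
MelB	4M64	2	46	63	54	W	W2.0
MelB	4M64	3	79	98	91	L	L3.0
MelB	4M64	4	107	129	117	G	G4.0
MelB	4M64	5	147	169	156	G	G5.0
MelB	4M64	6	178	196	186	L	L6.0
MelB	4M64	7	233	252	244	N	N7.0
MelB	4M64	8	272	291	279	N	N8.0
MelB	4M64	9	295	312	301	G	G9.0
MelB	4M64	10	332	347	337	G	G10.0
MelB	4M64	11	368	385	373	T	T11.0
MelB	4M64	12	415	432	420	L	L12.0
NarU	4IU8	1	37	56	44	L	L1.0
NarU	4IU8	2	73	91	83	G	G2.0
NarU	4IU8	3	101	119	110	L	L3.0
NarU	4IU8	4	130	147	139	G	G4.0
NarU	4IU8	5	167	187	172	G	G5.0
NarU	4IU8	6	211	229	218	V	V6.0
NarU	4IU8	7	254	277	258	S	S7.0
NarU	4IU8	8	290	307	304	S	S8.0
NarU	4IU8	9	316	334	322	N	N9.0
NarU	4IU8	10	347	367	362	G	G10.0
NarU	4IU8	11	405	423	408	S	S11.0
NarU	4IU8	12	431	454	447	V	V12.0
NRT1.1	5A2N	1	38	57	50	G	G1.0
NRT1.1	5A2N	2	70	91	88	G	G2.0
NRT1.1	5A2N	3	100	119	110	A	A3.0
NRT1.1	5A2N	4	147	166	161	G	G4.0
NRT1.1	5A2N	5	193	213	200	G	G5.0
NRT1.1	5A2N	6	218	237	232	L	L6.0
NRT1.1	5A2N	7	342	364	358	Q	Q7.0
NRT1.1	5A2N	8	381	399	383	S	S8.0
NRT1.1	5A2N	9	421	439	426	G	G9.0
NRT1.1	5A2N	10	462	481	475	G	G10.0
NRT1.1	5A2N	11	500	520	514	S	S11.0
NRT1.1	5A2N	12	542	561	554	L	L12.0
PiPT	4J05	1	39	56	46	A	A1.0
PiPT	4J05	2	74	92	84	G	G2.0
PiPT	4J05	3	106	123	113	I	I3.0
PiPT	4J05	4	133	151	143	G	G4.0
PiPT	4J05	5	173	195	180	G	G5.0
PiPT	4J05	6	209	227	222	A	A6.0
PiPT	4J05	7	313	333	333	N	N7.0
PiPT	4J05	8	358	377	361	N	N8.0
PiPT	4J05	9	385	404	392	G	G9.0
PiPT	4J05	10	415	436	429	G	G10.0
PiPT	4J05	11	452	469	470	N	N11.0	anchor_outside_printed_span
PiPT	4J05	12	481	499	482	L	L12.0
YajR	3WDO	1	14	33	26	L	L1.0
YajR	3WDO	2	51	69	58	G	G2.0
YajR	3WDO	3	79	98	85	L	L3.0
YajR	3WDO	4	102	119	112	G	G4.0
YajR	3WDO	5	136	155	141	G	G5.0
YajR	3WDO	6	165	183	179	I	I6.0
YajR	3WDO	7	215	234	218	N	N7.0
YajR	3WDO	8	250	268	264	V	V8.0
YajR	3WDO	9	279	298	286	G	G9.0
YajR	3WDO	10	303	325	308	G	G10.0
YajR	3WDO	11	340	361	346	S	S11.0
YajR	3WDO	12	368	386	378	A	A12.0
YgbH	4Q65	1	13	33	27	G	G1.0
YgbH	4Q65	2	49	67	65	G	G2.0
YgbH	4Q65	3	78	95	83	A	A3.0
YgbH	4Q65	4	101	120	115	G	G4.0
YgbH	4Q65	5	142	161	150	G	G5.0
YgbH	4Q65	6	169	187	182	L	L6.0
YgbH	4Q65	7	267	289	285	Q	Q7.0
YgbH	4Q65	8	311	331	315	S	S8.0
YgbH	4Q65	9	342	362	351	G	G9.0
YgbH	4Q65	10	379	400	388	G	G10.0
YgbH	4Q65	11	414	433	427	N	N11.0
YgbH	4Q65	12	461	480	470	V	V12.0
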