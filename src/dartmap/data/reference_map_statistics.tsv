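linkage_group	full_markers	full_dart	full_ssr	full_cm	framework_markers	framework_dart	framework_ssr	framework_cm	fw2g_markers	physical_mbp	ratio_kbp_per_cm
1	207	191	16	167.8	80	72	8	114.0	62	40.7	357.3
2	244	219	25	129.0	131	112	19	122.1	98	63.8	522.1
3	270	256	14	102.4	128	115	13	124.6	102	79.7	639.2
4	106	93	13	86.6	57	44	13	76.1	52	41.1	539.9
5	189	166	23	130.7	74	54	20	100.3	68	73.8	736.1
6	271	231	40	116.5	104	72	32	121.6	88	50.3	413.7
7	224	210	14	117.3	75	64	11	130.5	68	51.9	548.4
8	275	262	13	118.6	107	95	12	116.2	94	68.4	588.9
9	220	204	16	118.3	78	64	14	92.5	66	38.4	415.1
10	263	246	17	117.4	92	82	10	87.4	82	38.6	441.4
11	215	196	19	99.5	103	87	16	91.5	89	40.8	445.4
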