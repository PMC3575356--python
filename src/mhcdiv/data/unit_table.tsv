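variant	CS	GAI	SO	EM	SA	NCA	HO	NK	EC	WC	KH	SK
n_samples	5	21	1	13	1	12	36	23	8	53	3	9
Urth-DQB*0101	8	29	2	10	0	8	34	23	6	86	2	9
Urth-DQB*0102	0	0	0	0	0	0	0	0	0	2	0	0
Urth-DQB*0103	0	0	0	0	2	0	0	0	0	0	0	0
Urth-DQB*0104	0	0	0	0	0	0	0	0	2	0	0	0
Urth-DQB*0105	0	0	0	0	0	0	0	2	0	0	0	0
Urth-DQB*0106	0	0	0	0	0	0	0	0	0	2	0	0
Urth-DQB*0107	0	0	0	0	0	0	0	0	0	1	0	0
Urth-DQB*0108	0	0	0	0	0	0	1	0	0	0	0	0
Urth-DQB*0109	0	0	0	0	0	0	0	0	0	1	0	0
Urth-DQB*0201	0	2	0	5	0	5	4	2	0	0	2	2
Urth-DQB*0202	0	0	0	0	0	1	8	4	0	0	2	0
Urth-DQB*0301	0	0	0	1	0	2	1	0	0	8	0	2
Urth-DQB*0302	2	2	0	2	0	0	5	0	0	0	0	0
Urth-DQB*0401	0	0	0	2	0	0	2	12	3	0	0	0
Urth-DQB*0402	0	0	0	0	0	0	0	1	0	0	0	0
Urth-DQB*0403	0	0	0	0	0	0	1	0	0	0	0	0
Urth-DQB*0501	0	0	0	0	0	0	2	0	0	0	0	0
Urth-DQB*0601	0	0	0	0	0	0	2	0	0	0	0	0
Urth-DQB*0701	0	9	0	5	0	2	0	0	1	0	0	2
Urth-DQB*0801	0	0	0	0	0	2	0	0	0	0	0	0
Urth-DQB*0901	0	0	0	0	0	0	0	0	0	2	0	0
Urth-DQB*1001	0	0	0	0	0	0	0	0	2	0	0	0
Urth-DQB*1101	0	0	0	0	0	0	0	0	0	0	0	2
Urth-DQB*1201	0	0	0	0	0	0	2	0	0	0	0	0
Urth-DQB*1301	0	0	0	0	0	0	2	0	0	0	0	0
Urth-DQB*1401	0	0	0	0	0	0	2	0	0	0	0	0
Urth-DQB*1501	0	0	0	0	0	0	0	0	0	2	0	0
Urth-DQB*1601	0	0	0	0	0	0	2	0	0	0	0	0
Urth-DQB*1701	0	0	0	1	0	0	0	0	0	0	0	0
Urth-DQB*1801	0	0	0	0	0	0	1	0	0	0	0	0
Urth-DQB*1901	0	0	0	0	0	0	0	1	0	0	0	0
Urth-DQB*2001	0	0	0	0	0	0	0	1	0	0	0	0
Urth-DQB*2101	0	0	0	0	0	1	0	0	0	0	0	0
Urth-DQB*2201	0	0	0	0	0	1	0	0	0	0	0	0
Urth-DQB*2301	0	0	0	0	0	1	0	0	0	0	0	0
Urth-DQB*2401	0	0	0	0	0	1	0	0	0	0	0	0
Urth-DQB*2501	0	0	0	0	0	0	1	0	0	0	0	0
Urth-DQB*2601	0	0	0	0	0	0	0	0	1	0	0	0
Urth-DQB*2701	0	0	0	0	0	0	1	0	0	0	0	0
Urth-DQB*2801	0	0	0	0	0	0	1	0	0	0	0	0
Urth-DQB*2901	0	0	0	0	0	0	0	0	0	1	0	0
Urth-DQB*3001	0	0	0	0	0	0	0	0	0	0	0	1
Urth-DQB*3101	0	0	0	0	0	0	0	0	1	0	0	0
Urth-DQB*3201	0	0	0	0	0	0	0	0	0	1	0	0
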