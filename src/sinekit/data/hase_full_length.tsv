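name	accession	start	end	length	identity_pct	gc5	gc3
HaSE1.1	JQ308191	1082	759	324	81	ND	ND
HaSE1.2-1	FP340421	20817	21088	272	81	37	32
HaSE1.2-2	FP340425	2038	2309	272	81	37	32
HaSE1.3-1	FP340422	76725	77124	400	95	41	41
HaSE1.3-2	FP340436	65754	65354	401	95	35	36
HaSE1.4	FP340423	15381	15782	402	97	33	38
HaSE1.5-1	FP340434	83754	84151	398	93	40	41
HaSE1.5-2	FP340425	33395	32998	398	93	40	41
HaSE1.5-3	FP340421	52178	51781	398	93	40	41
HaSE1.5-4	FP340430	3597	3200	398	93	40	37
HaSE1.6	FP340427	56774	57163	390	96	40	39
HaSE1.7	FP340428	23925	23540	386	96	35	36
HaSE1.8	FP340430	48647	49045	399	96	36	35
HaSE1.9	FP340430	63322	62941	382	94	36	31
HaSE1.10-1	FP340430	10685	10341	345	83	37	37
HaSE1.10-2	FP340434	76862	77152	291	80	38	35
HaSE1.10-3	FP340425	40287	39997	291	80	38	35
HaSE1.10-4	FP340421	59070	58780	291	80	38	35
HaSE1.11-1	FP340430	59655	60021	361	77	34	29
HaSE1.11-2	FP340421	106276	106636	361	79	35	29
HaSE1.11-3	FP340425	87493	87853	361	79	35	29
HaSE1.11-4	FP340434	29656	29296	361	79	35	29
HaSE1.12	FP340432	12205	11822	384	96	40	38
HaSE1.13	FP340432	92706	93093	388	97	39	38
HaSE1.14	FP340437	3418	3033	386	95	34	35
HaSE1.15	FP340438	10122	10510	389	96	34	37
HaSE1.16	FP340438	5597	5977	381	97	36	36
HaSE1.17	FP340432	62457	62840	384	92	34	43
HaSE1.18-1	FP340437	61245	61648	404	86	34	36
HaSE1.18-2	FP340423	62742	63144	403	85	35	41
HaSE1.19	FP340422	92608	92224	385	95	40	38
HaSE1.20	FP340435	100427	100075	353	82	32	38
HaSE1.21	FP340435	71654	72034	381	80	35	42
HaSE1.22	EU920879	68	460	393	96	ND	ND
HaSE2.1	HQ453271	3805	3517	289	96	40	40
HaSE2.2-1	FP340425	94643	94943	301	97	33	30
HaSE2.2-2	FP340434	22506	22206	301	97	33	30
HaSE2.3	FP340437	75891	76196	306	94	38	36
HaSE2.4	FP340431	76086	75777	310	96	42	35
HaSE2.5	FP340433	83917	83633	285	97	39	37
HaSE2.6	FP340432	95944	95659	286	93	33	38
HaSE2.7	FP340435	124636	124393	244	66	33	35
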