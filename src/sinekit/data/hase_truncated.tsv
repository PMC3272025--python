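name	accession	start	end	length	tsd	gc5	gc3
HaSE1.23	FP340424	93555	93835	281	atgttatgggcatcgc	38	32
HaSE1.24	FP340424	88889	88588	302	aatcagaag	31	35
HaSE1.25	FP340433	3655	3925	271	agagctgaatcagctg	35	36
HaSE1.26	FP340437	33829	34075	247	taatttt	31	33
HaSE1.27	FP340438	19747	19470	278	atcctcta(g)cagtc	38	35
HaSE1.28	FP340421	1032	1387	356	aaggggtaa	35	35
HaSE1.29-1	FP340425	747	491	257	atctta	35	38
HaSE1.29-2	FP340421	19526	19270	257	atctta	35	37
HaSE1.30	FP340421	9640	9754	115	ataaaagtatgtcttg	34	37
HaSE1.31	FP340435	88927	88681	247	atttctc	34	35
HaSE1.32	FP340435	105108	105257	150	tgatga	38	34
HaSE1.33	FP340431	1576	1733	158	tggtttt	38	40
HaSE1.34	FP340421	9640	9754	115	ataaaagtatgtcttg	34	37
HaSE1.35	FP340435	57601	57855	255	aactagtact	37	38
HaSE1.36	FP340435	55804	55957	154	tggaaagcta	38	38
HaSE1.37	FP340435	13183	13068	116	atatttttt	35	33
HaSE1.38	FP340435	111769	111913	145	acagggaag	29	31
HaSE1.39	FP340435	52746	52855	110	gtattttagaccccg	46	38
HaSE1.40	FP340437	30962	31090	129	ttacccagaaatcaa	37	32
HaSE1.41	FP340433	27046	27120	75	tggctgaaaagaaatga	32	34
HaSE1.42	FP340435	21259	21074	186	ttactttagcagct	37	33
HaSE1.43	FP340427	24173	24329	157	gaaaaagcacttaagg	40	47
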