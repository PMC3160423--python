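# New miRNAs and new members of known miRNA families with detected miRNA*s
# (published Medicago truncatula drought study summary table; packaged as a
# worked-example fixture). counts column is "mature/star"; the miR5555 star
# count was not printed and is left empty after the slash convention.
name	sequence	length_nt	count_mature	count_star	location	arm	precursor_len	mfe_kcal_mol	group
miR5213	uacgugugucuucaccucugaa	22	15045	44	MtChr2:16737666:16737796:+	5'	131	-43.1	new_miRNA
miR5274b	auaugacggaguguaaaugcc	21	29	2	MtChr4:11424365:11424459:-	5'	95	-66.3	new_miRNA
miR5554a	ugugcaucuugaacaaugguau	22	134	3	MtChr1:31285750:31285854:-	5'	105	-52.8	new_miRNA
miR5554b	ugugcaucuugaacaaugguau	22	134	3	MtChr4:41013393:41013497:-	5'	105	-57.3	new_miRNA
miR5554c	ugugcaucuugaacaaugguau	22	134	1	MtChr7:19742691:19742795:-	5'	105	-53.3	new_miRNA
miR5555	uaagaguauaauaugacuuug	21	40664		MtChr1:12905862:12905956:-	5'	95	-47.5	new_miRNA
miR5556	ugaugacggaagaaauccaaa	21	155	1	MtChr4:23199944:23200064:-	3'	121	-54.8	new_miRNA
miR5557	ugcuuccuuaguacuuguuga	21	5	3	MtChr5:6026167:6026481:+	3'	315	-96.7	new_miRNA
miR5558	uuuuccaauucuaagucuauc	21	139	8	MtChr5:20521087:20521172:+	5'	86	-33	new_miRNA
miR5559	uacuuggugaauuguuggauc	21	2124	2	MtChr6:937306:937443:+	5'	138	-48.8	new_miRNA
miR5560	ugccggcucaaugaaugcggag	22	62	2	MtChr6:4747428:4747538:+	3'	111	-53.8	new_miRNA
miR5561	cauuuggagagacauagacaa	21	449	3	MtChr7:30170572:30170660:-	5'	89	-42.9	new_miRNA
miR5562	uguggagucuuuugcaugaag	21	16	1	MtChr7:32194444:32194667:-	5'	224	-56.4	new_miRNA
miR5563	ugauaucaggcaacucggucc	21	12	1	MtChr8:32699524:32699624:-	5'	101	-52.9	new_miRNA
miR156j	uugacagaagagggugagcaca	22	10341	23	MtChr1:3228429:3228554:+	5'	126	-44.4	new_member
miR167b	ugaagcugccagcaugaucug	21	40937	1	MtChr7:34009590:34009796:+	5'	207	-78.7	new_member
miR168c	ucgcuuggugcaggucgggaa	21	56024	1434	MtChr5:10397699:10397824:+	5'	126	-68.8	new_member
miR172b	agaaucuugaugaugcugcau	21	35344	63	AC235487:197944:198077:+	3'	134	-55.5	new_member
miR172c	agaaucuugaugaugcugcau	21	35386	8	AC233663:10168:10308:+	3'	141	-52.8	new_member
miR408	augcacugccucuucccuggc	21	75	55	MtChr1:21952074:21952198:+	3'	125	-45.1	new_member
miR2111u	uaaucugcauccugagguuua	21	413	23	MtChr7:14331003:14331117:-	5'	115	-50.2	new_member
miR2111v	uaaucugcauccugagguuua	21	1192	41	MtChr7:14356392:14356499:-	5'	108	-48.4	new_member
miR2592a	gaaaaacaugaaugucgagcg	21	28	1	MtChr1:27380857:27381050:+	3'	194	-89.4	new_member
miR2592bl	uggcaaguuugaauuuaccuca	22	43	1	MtChr4:18239825:18239954:+	5'	130	-69.3	new_member
miR2592bm	ggaaaacaugaaugucgggug	21	918	294	MtChr5:3041012:3041204:+	3'	193	-104.4	new_member
miR2592bn	ggaaaacaugaaugucgggug	21	530	160	MtChr5:8400182:8400375:+	3'	194	-111.8	new_member
miR2619b	auauguuuugauucuuuggca	21	9	3	MtChr4:6335670:6335840:+	5'	171	-94.7	new_member
miR2643b	uuugggaucagaaauuagaga	21	361	11	MtChr5:41836449:41836558:-	3'	110	-38.8	new_member
miR4414a	agcugcugacucguugguuca	21	663	45	MtChr1:30518803:30518924:+	5'	122	-50.5	new_member
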