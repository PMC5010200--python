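name	length_min	length_max	aligned_length	n_vc	pct_vc_printed	n_pic	pct_pic_printed
rps18-rpl20	283	326	332	30	9.04	9	2.71
trnT(GUG)-trnL(UAA)	523	636	639	50	7.82	27	4.23
trnG(UCC)-trnR(UCU)	341	408	448	35	7.81	8	1.79
atpF-atpH	397	437	449	28	6.24	11	2.45
petN-psbM	609	754	756	47	6.22	14	1.85
rpl32-trnL(UAG)	760	787	813	48	5.90	6	0.74
ndhC-trnV(UAC)	921	1200	1234	71	5.75	15	1.22
ndhF-rpl32	735	953	980	54	5.51	8	0.82
trnC(GCA)-petN	712	743	765	41	5.42	8	1.06
rps16-trnQ(UUG)	869	1478	1544	78	5.05	11	0.72
petA-psbL	963	978	1010	50	4.95	11	0.73
trnE(UUC)-trnT(GGU)	793	823	832	40	4.81	7	0.84
trnP(UGG)-psaJ	398	400	403	19	4.71	5	1.24
rpoB-trnC(GCA)	1139	1265	1271	57	4.48	7	0.55
ndhG-ndhI	264	357	357	16	4.48	5	1.40
trnF(GAA)-ndhJ	692	714	722	32	4.43	11	1.52
ycf4-cemA	653	950	951	37	3.89	6	0.63
psaA-ycf3	730	749	764	29	3.80	15	1.96
atpH-atpI	1107	1149	1196	45	3.76	8	0.67
ycf3-trnS(GGA)	823	831	832	31	3.73	8	0.96
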