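rsid	gene	variant_type	allele_label	maf_eur	maf_afr	maf_eas	maf_sas	maf_amr	maf_aj
rs2032582	ABCB1	Missense (A893S or A893T)	A	54.7	91.8	47.8	34.8	54.6	62.4
rs2032582	ABCB1	Missense (A893S or A893T)	S	41.8	7.8	38.9	60.9	40	35
rs2032582	ABCB1	Missense (A893S or A893T)	T	3.5	0.4	13.3	4.3	5.4	2.6
rs1128503	ABCB1	Synonymous	.	43.3	18.9	64.3	60.7	49.1	36.7
rs2229109	ABCB1	Missense (S400N)	.	4.3	0.7	0	1.5	1.7	2.8
rs1045642	ABCB1	Synonymous	.	53.4	20	36.7	39.5	45.4	35.6
rs9282564	ABCB1	Missense (N21D)	.	10.8	1.6	<0.1	2.4	2.9	2.4
rs3213619	ABCB1	5' UTR	.	4.0	8.4	3.8	.	4.7	3.0
rs12720066	ABCB1	Intron	.	5.5	10	.	.	3.5	5.2
rs4148737	ABCB1	Intron	.	42.9	44.9	28.9	.	41.4	48.6
rs3842	ABCB1	3' UTR	.	13.6	16.9	26.2	.	14.2	17.5
rs10267099	ABCB1	Intron	.	77.1	83.2	99.7	.	86.3	73.5
rs45511401	ABCC1	Missense (G671V)	.	5.6	1.2	<0.1	1.6	1.7	3.3
rs4148350	ABCC1	Intron	.	7.3	10.4	4.0	.	8.4	6.6
rs246221	ABCC1	Synonymous	.	30.5	65.2	42.5	20.3	35.2	32.1
rs3743527	ABCC1	3' UTR	.	22.6	14.3	45.7	.	27.0	23.8
rs17501331	ABCC1	Intron	.	10.3	2.2	0	.	5.8	11.7
rs212091	ABCC1	3' UTR	.	14.9	13.0	25.4	.	10.2	9.7
rs119774	ABCC1	Intron	.	6.8	1.6	0.3	.	4.4	6.9
rs2074087	ABCC1	Intron	.	84.4	81.5	82.5	68.2	78.9	77.0
rs8187710	ABCC2	Missense (C1515Y)	.	5.6	15.7	<0.1	1.9	4.1	12.9
rs3740065	ABCC2	Intron	.	9.7	21.6	34.1	.	14.0	17.2
rs3740066	ABCC2	Synonymous	.	37	25.9	23	32.6	34.9	34.5
rs12762549	ABCC2	Intergenic	.	46.8	43.0	56.5	.	49.3	51.7
rs717620	ABCC2	5' UTR	.	19.9	5.8	21.4	11.3	13.0	20.0
rs17222723	ABCC2	Missense (V1188E)	.	5.6	6.0	<0.1	1.8	3.6	12.8
rs1051640	ABCC3	Synonymous	.	18.2	8.6	5.6	10.3	8.6	18.7
rs4148416	ABCC3	Synonymous	.	5.4	19.6	15.0	8.8	14.4	5.8
rs4148405	ABCC3	Intron	.	14	43.7	21.7	.	21.8	21
rs2274405	ABCC4	Synonymous	.	34.1	30.3	47.1	36.1	42.7	46.4
rs3749438	ABCC5	3' UTR	.	36.1	26.2	40.6	.	28.4	39.7
rs10937158	ABCC5	Intron	.	54.4	74.7	86.0	.	51.0	53.3
rs7627754	ABCC5	Promoter	.	11.4	36.0	34.9	.	18.5	7.6
rs7636910	ABCC5	Synonymous	.	36.9	26.8	41.5	36.4	26.9	40.9
rs2238472	ABCC6	Missense (R1268Q)	.	28.2	10.1	12.3	18.2	31.3	17.0
rs2125739	ABCC10	Missense (I948T)	.	25.1	31.9	10.9	18.0	18.7	21.3
rs17822931	ABCC11	Missense (G180R)	.	13	2.8	87	40.6	16.2	10.8
rs2231135	ABCG2	5' UTR	.	7.0	2.0	0	.	4.3	4.0
rs2231142	ABCG2	Missense (Q141K)	.	10.4	2.7	30.7	9.3	22.6	6.6
rs2231137	ABCG2	Missense (V12M)	.	4.1	6.6	32.8	14.0	23.7	10.5
rs7699188	ABCG2	Intron	.	15.6	44.1	7.6	.	13.2	23.1
rs3109823	ABCG2	Intron	.	71.8	44	78.8	.	80.6	83.4
rs13120400	ABCG2	Intron	.	30.5	6.2	0	.	14.7	17.4
rs2199936	ABCG2	Intron	.	89.4	87.6	67.1	.	80.9	92.8
rs4148155	ABCG2	Intron	.	10.5	2.3	32.8	.	18.6	6.6
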