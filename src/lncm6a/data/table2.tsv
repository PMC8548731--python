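Chr	Peak_start	Peak_end	Strand	Ensembl_ID	Gene_Name	RNA-seq_log2FoldChange	RNA-seq_padj	MeRIP-seq_diff.log2.fc	MeRIP-seq_diff.lg.fdr	Gene_Type	Group
11	115946568	115946986	-	ENSMUSG00000087064	Sap30bpos	4.068002111	0.000201133	4.75	-1.71	antisense	Hyper-up
17	70800582	70800823	-	ENSMUSG00000117231	Gm41609	2.740191127	0.003528931	4.74	-1.37	processed_transcript	Hyper-up
7	143257440	143257921	-	ENSMUSG00000101609	Kcnq1ot1	0.575398413	0.013352397	3.31	-1.51	antisense	Hyper-up
8	123899672	123900620	+	ENSMUSG00000110547	Gm29773	4.214800444	4.74E-15	2.32	-3.89	antisense	Hyper-up
X	103469670	103469796	-	ENSMUSG00000086503	Xist	1.181915678	6.27E-20	1.97	-49	lincRNA	Hyper-up
7	59970257	59973787	-	ENSMUSG00000100826	Snhg14	1.035494247	0.000971565	1.87	-6.16	processed_transcript	Hyper-up
17	29059068	29059722	+	ENSMUSG00000117007	Gm41556	3.003943093	0.001225038	1.83	-1.4	lincRNA	Hyper-up
6	54269710	54270309	-	ENSMUSG00000073067	9130019P16Rik	2.455499081	2.29E-06	1.78	-1.7	processed_transcript	Hyper-up
9	35126228	35126888	+	ENSMUSG00000070315	4930581F22Rik	0.617762934	0.032115595	1.19	-5.53	processed_transcript	Hyper-up
15	56694041	56765501	+	ENSMUSG00000086541	Has2os	1.24715012	0.012876036	1.03	-6.52	processed_transcript	Hyper-up
1	150159072	150159782	-	ENSMUSG00000097754	Ptgs2os2	-3.338667012	1.71E-06	-3.09	-2.46	lincRNA	Hypo-down
1	91801436	91801917	-	ENSMUSG00000100980	Gm29100	-1.386873948	0.044030192	-0.922	-1.41	antisense	Hypo-down
5	136933475	136934126	+	ENSMUSG00000097908	4933404O12Rik	-2.110740583	6.83E-22	-0.891	-1.35	lincRNA	Hypo-down
9	44112922	44113191	+	ENSMUSG00000097467	Gm26737	-2.335487486	1.12E-07	-0.849	-1.99	antisense	Hypo-down
11	86209134	86209584	+	ENSMUSG00000085208	Brip1os	-2.020791677	2.06E-50	-0.631	-3.96	antisense	Hypo-down
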