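Ensembl_ID	Gene_Name	Expression	log2FoldChange	meanfpkm	padj
ENSMUSG00000087591	Gm14635	Up	9.478458245	6.5058287	2.95E-10
ENSMUSG00000110071	Gm45512	Up	8.979513546	4.7889075	3.66E-09
ENSMUSG00000108322	5430431A17Rik	Up	8.917522207	18.467968	3.13E-11
ENSMUSG00000099906	Gm28653	Up	6.761660182	29.802335	4.47E-115
ENSMUSG00000099465	Gm3830	Up	6.719594193	3.649369	4.34E-18
ENSMUSG00000112963	Gm6093	Up	6.600023017	6.7770027	4.89E-51
ENSMUSG00000101746	2310043L19Rik	Up	6.259516887	3.2733601	3.43E-08
ENSMUSG00000104045	Gm37565	Up	5.616399462	8.984661	1.25E-16
ENSMUSG00000109962	1700025L06Rik	Up	5.062787459	3.0317699	3.23E-27
ENSMUSG00000085208	Brip1os	Down	-2.020791677	11.071526	2.06E-50
ENSMUSG00000097908	4933404O12Rik	Down	-2.110740583	3.1048072	6.83E-22
ENSMUSG00000100798	Gm19589	Down	-2.141593862	2.0967695	7.30E-12
ENSMUSG00000110350	Gm10252	Down	-2.36282624	2.0370561	6.34E-05
ENSMUSG00000063018	2010204K13Rik	Down	-2.962399389	2.6803628	6.84E-14
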