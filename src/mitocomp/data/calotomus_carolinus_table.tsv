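gene	kind	start	stop	length	intergenic	start_codon	stop_codon	anticodon	strand
tRNA-Phe	tRNA	1	69	69	0			GAA	H
12S-rRNA	rRNA	70	1020	951	0				H
tRNA-Val	tRNA	1021	1093	73	0			TAC	H
16S-rRNA	rRNA	1094	2782	1689	0				H
tRNA-Leu(UAA)	tRNA	2783	2855	73	0			TAA	H
ND1	PCG	2856	3830	975	7	ATG	TAA		H
tRNA-Ile	tRNA	3838	3907	70	10			GAT	H
tRNA-Met	tRNA	3918	3986	69	6			TTG	H
tRNA-Gln	tRNA	3993	4063	71	68			CAT	L
ND2	PCG	4132	5176	1045	0	ATG	TAG		H
tRNA-Trp	tRNA	5177	5247	71	4			TCA	H
tRNA-Ala	tRNA	5252	5322	71	5			TGC	L
tRNA-Asn	tRNA	5328	5400	73	41			GTT	L
tRNA-Cys	tRNA	5442	5507	66	9			GCA	L
tRNA-Tyr	tRNA	5517	5586	70	1			GTA	L
COI	PCG	5588	7138	1551	0	GTG	TAA		H
tRNA-Ser(UGA)	tRNA	7139	7209	71	3			TGA	L
tRNA-Asp	tRNA	7213	7283	71	4			GTC	H
COII	PCG	7288	7978	691	0	ATG	T		H
tRNA-Lys	tRNA	7979	8052	74	1			TTT	H
ATP8	PCG	8054	8221	168	-16	ATG	TAG		H
ATP6	PCG	8206	8894	689	0	CTG	TA		H
COIII	PCG	8895	9679	785	0	ATG	TAA		H
tRNA-Gly	tRNA	9680	9750	71	1			TCC	H
ND3	PCG	9752	10103	352	0	ATA	TAG		H
tRNA-Arg	tRNA	10104	10172	69	0			TCG	H
ND4L	PCG	10173	10469	297	-7	ATG	TAA		H
ND4	PCG	10463	11843	1381	0	ATG	T		H
tRNA-His	tRNA	11844	11912	69	2			GTG	H
tRNA-Ser(GCU)	tRNA	11915	11980	66	32			GCT	H
tRNA-Leu(UAG)	tRNA	12013	12084	72	4			TAG	H
ND5	PCG	12089	13930	1842	-4	ATG	TAA		H
ND6	PCG	13927	14448	522	1	ATG	TAA		L
tRNA-Glu	tRNA	14450	14522	73	64			TTC	L
Cytb	PCG	14587	15727	1141	0	ATG	T		H
tRNA-Thr	tRNA	15728	15799	72	0			TGT	H
tRNA-Pro	tRNA	15800	15872	73	0			TGG	L
CR	CR	15873	17114	1242	0				H
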