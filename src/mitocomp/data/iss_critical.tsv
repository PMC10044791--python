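# Critical saturation-index (Iss.c) calibration table.
# Derived by simulation: Jukes-Cantor evolution on symmetric/asymmetric
# trees over a depth sweep; Iss.c = Iss at the depth where neighbour-joining
# bipartition recovery falls through 0.95 (40 replicates/depth, isotonic in L).
# seed=20230307; entropy-index method per the saturation module docs.
topology	n_taxa	length	iss_c	note
asymmetric	4	100	0.7416	crossing
asymmetric	4	200	0.8004	crossing
asymmetric	4	400	0.9018	crossing
asymmetric	4	800	0.9218	crossing
asymmetric	4	1600	0.9628	crossing
asymmetric	4	3200	0.9650	crossing
asymmetric	4	6400	0.9669	crossing
asymmetric	8	100	0.7299	crossing
asymmetric	8	200	0.8387	crossing
asymmetric	8	400	0.8765	crossing
asymmetric	8	800	0.9217	crossing
asymmetric	8	1600	0.9305	crossing
asymmetric	8	3200	0.9560	crossing
asymmetric	8	6400	0.9705	crossing
asymmetric	16	100	0.6632	crossing
asymmetric	16	200	0.7714	crossing
asymmetric	16	400	0.8108	crossing
asymmetric	16	800	0.8568	crossing
asymmetric	16	1600	0.9262	crossing
asymmetric	16	3200	0.9395	crossing
asymmetric	16	6400	0.9645	crossing
asymmetric	32	100	0.3536	peak
asymmetric	32	200	0.6054	crossing
asymmetric	32	400	0.6936	crossing
asymmetric	32	800	0.7389	crossing
asymmetric	32	1600	0.7670	crossing
asymmetric	32	3200	0.8249	crossing
asymmetric	32	6400	0.8542	crossing
symmetric	4	100	0.9211	crossing
symmetric	4	200	0.9313	crossing
symmetric	4	400	0.9683	crossing
symmetric	4	800	0.9718	crossing
symmetric	4	1600	0.9751	crossing
symmetric	4	3200	0.9913	crossing
symmetric	4	6400	0.9914	crossing
symmetric	8	100	0.6566	crossing
symmetric	8	200	0.7258	crossing
symmetric	8	400	0.8128	crossing
symmetric	8	800	0.8384	crossing
symmetric	8	1600	0.9019	crossing
symmetric	8	3200	0.9148	crossing
symmetric	8	6400	0.9232	crossing
symmetric	16	100	0.6470	crossing
symmetric	16	200	0.7658	crossing
symmetric	16	400	0.8485	crossing
symmetric	16	800	0.8741	crossing
symmetric	16	1600	0.9216	crossing
symmetric	16	3200	0.9464	crossing
symmetric	16	6400	0.9828	crossing
symmetric	32	100	0.6560	crossing
symmetric	32	200	0.7958	crossing
symmetric	32	400	0.8655	crossing
symmetric	32	800	0.8910	crossing
symmetric	32	1600	0.9430	crossing
symmetric	32	3200	0.9858	crossing
symmetric	32	6400	0.9875	crossing
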