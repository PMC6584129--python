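# Predicted specialized metabolic gene clusters of Streptomyces venezuelae ATCC 10712
# (antiSMASH predictions; locus spans as first/last SVEN locus tags), with the number of
# genes up-/down-regulated on loss of the Lsr2 silencer (q < 0.01, >4 fold change), the
# printed percentage of upregulated genes per cluster, and the number of Lsr2-associated
# ChIP sites (q < 0.01) in each cluster.
name	product	first_locus	last_locus	n_upregulated	n_repressed	pct_upregulated	n_sites
Ectoine		SVEN_0223	SVEN_0234	1	0	8.33	0
Terpene		SVEN_0261	SVEN_0306	1	0	0	0
T1PKS-T3PKS-NRPS	venemycin/watasemycin/thiazostatin	SVEN_0463	SVEN_0531	28	0	42.65	2
Lantipeptide-terpene		SVEN_0540	SVEN_0561	0	0	0	1
Lantipeptide	venezuelin	SVEN_0612	SVEN_0630	3	1	16.67	0
Indole	acryriaflavin	SVEN_0755	SVEN_0772	0	0	0	0
Chloramphenicol	chloramphenicol	SVEN_0913	SVEN_0928	14	0	93.33	1
Other		SVEN_1844	SVEN_1884	0	0	0	0
Siderophore	desferrioxamine-like	SVEN_2566	SVEN_2577	5	0	41.67	1
Lassopeptide		SVEN_3103	SVEN_3132	2	0	6.90	1
Other		SVEN_4061	SVEN_4110	1	0	2.04	1
Butyrolactone	gaburedin	SVEN_4179	SVEN_4189	0	0	0	0
Melanin		SVEN_4620	SVEN_4662	0	0	0	4
Butyrolactone		SVEN_5076	SVEN_5111	3	0	11.54	2
Thiopeptide		SVEN_5119	SVEN_5145	3	0	11.54	3
T3pks		SVEN_5351	SVEN_5383	0	0	0	0
Siderophore		SVEN_5413	SVEN_5426	0	0	0	0
Siderophore		SVEN_5471	SVEN_5482	0	1	9.09	0
Bacteriocin		SVEN_5817	SVEN_5840	3	0	15.15	1
Butyrolactone-T2PKS		SVEN_5951	SVEN_6002	19	0	45.10	6
Other		SVEN_6112	SVEN_6204	3	1	3.26	1
NRPS-ladderane		SVEN_6134	SVEN_6282	50	0	36.49	7
Terpene		SVEN_6436	SVEN_6490	6	0	16.67	1
Bacteriocin		SVEN_6527	SVEN_6535	0	1	0	0
T2PKS		SVEN_6767	SVEN_6814	2	0	4.26	0
Melanin		SVEN_6833	SVEN_6842	4	0	44.44	0
NRPS		SVEN_7032	SVEN_7080	0	0	0	0
Terpene		SVEN_7101	SVEN_7119	0	2	0	1
T3PKS		SVEN_7223	SVEN_7259	1	0	2.78	2
Terpene-NRPS		SVEN_7417	SVEN_7452	0	0	0	4
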