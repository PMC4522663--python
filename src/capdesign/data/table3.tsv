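sample	pool	bp_covered_plus	pct_covered_plus	bp_covered_cds	pct_covered_cds
1	1	145066553	95.6	67225626	94.3
2	1	145081909	95.6	67250020	94.4
3	1	144607207	95.3	67007231	94.0
4	1	143036351	94.3	66060290	92.7
5	2	145147282	95.7	67070797	94.1
6	2	143617018	94.7	66121333	92.8
7	2	144051293	95.0	66351108	93.1
8	2	145267122	95.8	67097056	94.2
9	3	144802496	95.5	66904165	93.9
10	3	143126270	94.3	65865667	92.4
11	3	144861681	95.5	66904165	93.9
12	3	144585713	95.3	66786409	93.7
13	4	142170547	93.7	65328731	91.7
14	4	143170286	94.4	66018207	92.7
15	4	145360509	95.8	67273067	94.4
16	4	143449544	94.6	66120048	92.8
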