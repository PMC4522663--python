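sample	pool	total_reads	mapped_reads	duplicate_reads	remaining_reads	remaining_pct	depth_x
1	1	284357886	264735195	9414179	255321016	89.8	85.8
2	1	281522490	261170320	9366318	251804002	89.4	84.3
3	1	249659670	231433861	7819714	223614147	89.6	75.4
4	1	181728820	168679105	4382284	164296821	90.4	55.5
5	2	266996086	251028902	17002907	234025995	87.7	75.3
6	2	187857302	176207940	12226544	163981396	87.3	53.9
7	2	233403500	216361182	13330685	203030497	87.0	65.0
8	2	314005584	289641450	23514154	266127296	84.8	82.9
9	3	262726150	246019167	14919187	231099980	88.0	74.8
10	3	181120464	169294819	10140076	159154743	87.9	51.6
11	3	269017896	247287291	16377215	230910076	85.8	73.1
12	3	243350554	227421662	12820659	214601003	88.2	69.5
13	4	154004914	142631944	9095086	133536858	86.7	42.6
14	4	193942804	175552484	13670936	161881548	83.5	50.1
15	4	221094842	204380382	15086795	189293587	85.6	59.5
16	4	364079702	337983155	31679889	306303266	84.1	93.9
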