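sample	pool	variants_plus	variants_cds
1	1	266334	118686
2	1	267695	119322
3	1	259499	115874
4	1	250196	110047
5	2	271834	118987
6	2	269445	117882
7	2	269995	118085
8	2	273081	119495
9	3	278462	122429
10	3	274222	119880
11	3	278688	122285
12	3	262793	116038
13	4	254919	111805
14	4	260454	114874
15	4	269313	118527
16	4	262786	114849
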