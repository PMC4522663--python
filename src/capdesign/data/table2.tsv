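sample	pool	n_regions_min_below	pct_min_below	n_regions_never	pct_never
1	1	42705	17.6	6977	2.9
2	1	42749	17.6	6980	2.9
3	1	45739	18.8	7307	3.0
4	1	55643	22.9	9346	3.8
5	2	41798	17.2	8502	3.5
6	2	54390	22.4	10953	4.5
7	2	50032	20.6	10439	4.3
8	2	40793	16.8	8238	3.4
9	3	44312	18.2	8884	3.7
10	3	57615	23.7	11185	4.6
11	3	44956	18.5	8698	3.6
12	3	46948	19.3	9125	3.8
13	4	66381	27.3	12380	5.1
14	4	57903	23.8	10446	4.3
15	4	41031	16.9	7457	3.1
16	4	54075	22.3	10156	4.2
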