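patient_id	tissue	sanger_604	aspcr_604	dpcr_call_604	dpcr_cpm_604	dpcr_rma_604	cold_call_604	cold_rma_604	sanger_605	aspcr_605	dpcr_call_605	dpcr_cpm_605	dpcr_rma_605	cold_call_605	cold_rma_605
1	BO	WT	WT	WT	0.181				WT	WT	MUT	0.892	>6
2	BO	WT	WT	WT	0.000				MUT	MUT	MUT	8.712	>50
3	BO	WT	WT	WT	0.095				MUT	MUT	MUT	17.626	100
4	BO	WT	WT	WT	0.000				WT	WT	WT	0.169
5	BO	WT	nd	WT	0.000		nd		WT	nd	MUT	6.594	50	nd
6	BO	WT	WT	WT	0.000		WT		WT	MUT	MUT	3.604	25	MUT	3
7	BO	WT	WT	WT	0.000				WT	WT	WT	0.000
8	BO	WT	WT	WT	0.086				WT	WT	WT	0.353
12	BO	WT	nd	WT	0.260		nd		WT	nd	MUT	3.196	25	nd
9	BO	WT	nd	WT	0.255		nd		WT	nd	WT	0.084		nd
37	BL	WT	WT	WT	0.166		WT		WT	WT	MUT	0.622	>6	MUT	6
37	BO-LJ	WT	WT	WT	0.195		WT		MUT	MUT	MUT	32.654	100	MUT	>40
37	BO-M	WT	nd	WT	0.000		nd		MUT	nd	MUT	22.108	100	nd
37	BO-RJ	WT	WT	WT	0.169		WT		WT	MUT	MUT	2.121	<25	MUT	3
37	BO-S	WT	nd	WT	0.188		nd		MUT	nd	MUT	22.904	100	nd
45	BL	WT	WT	WT	0.087				WT	WT	WT	0.312
45	BO	WT	WT	WT	0.092				WT	WT	WT	0.105
10	CB	WT	WT	WT	0.152				WT	WT	WT	0.343
11	CB	WT	WT	WT	0.237				WT	WT	WT	0.436
13	CB	WT	WT	WT	0.105				WT	WT	WT	0.100
14	CB	WT	WT	WT	0.000				WT	WT	WT	0.185
38	BL	WT	WT	WT	0.000				WT	WT	WT	0.178
38	CB-WT	WT	WT	WT	0.183				WT	nd	WT	0.233
38	CB-YT	WT	WT	WT	0.105				WT	nd	WT	0.416
38	CB-GT	WT	WT	WT	0.173				WT	nd	WT	0.191
39	BL	WT	WT	WT	0.319				WT	WT	MUT	0.509	6
39	CB	WT	WT	WT	0.000				WT	WT	MUT	1.251	<12.5
52	BL	WT	WT	WT	0.112		nd		WT	MUT	MUT	0.598	6	nd
52	CB	WT	WT	WT	0.000		nd		WT	MUT	MUT	6.208	50	nd
40	BL	WT	WT	WT	0.000		WT		WT	WT	WT	0.096		WT
40	CB	WT	WT	WT	0.320		nd		WT	WT	WT	0.139		WT
41	BL	WT	WT	MUT	2.249	<12.5	MUT	<2.5	WT	WT	WT	0.254		WT
41	CB-GT	WT	WT	WT	0.104				WT	WT	WT	0.078
41	CB-WT	WT	WT	WT	0.000		nd		WT	WT	WT	0.336		nd
41	CB-YT	WT	WT	WT	0.000				WT	WT	WT	0.180
42	BL	WT	WT	WT	0.223		WT		WT	WT	WT	0.083		WT
42	FB	WT	WT	WT	0.265		WT		WT	WT	WT	0.190		WT
43	BL	WT	WT	WT	0.188				WT	WT	MUT	0.873	>6
43	CB	WT	WT	WT	0.000				WT	WT	WT	0.089
43	FB	WT	WT	WT	0.000				WT	WT	MUT	1.633	>12.5
35	OT	WT	nd	WT	0.000				WT	nd	WT	0.244
44	BL	WT	WT	MUT	0.777	<3	WT		WT	WT	WT	0.293		WT
44	OCL	WT	WT	MUT	4.995	<25	MUT	<2.5	WT	WT	WT	0.256		WT
44	OT	WT	WT	MUT	1.485	>6	WT		WT	WT	WT	0.184		WT
46	OC	WT	WT	WT	0.083		WT		MUT	MUT	MUT	2.969	<25	MUT	10
46	OT	WT	WT	WT	0.182		WT		WT	WT	MUT	0.520	6	MUT	<0.5
47	BL	WT	WT	WT	0.000		WT		WT	WT	WT	0.299		WT
47	OC	WT	WT	WT	0.102		WT		WT	WT	MUT	1.135	<12.5	WT
47	OT	WT	WT	WT	0.084		WT		WT	WT	MUT	1.164	<12.5	MUT	3
48	BL	WT	WT	WT	0.334		WT		WT	MUT	MUT	5.347	<50	MUT	16
48	OC	WT	WT	WT	0.000		WT		WT	MUT	MUT	10.169	>50	MUT	>40
49	BL	WT	WT	WT	0.101		WT		WT	WT	MUT	0.465	3	WT
49	OC	WT	WT	WT	0.192		WT		WT	WT	MUT	1.578	>12.5	MUT	26
50	OC	WT	WT	WT	0.412		WT		WT	MUT	MUT	3.312	25	MUT	<0.5
50	OCL	WT	WT	WT	0.205		WT		WT	MUT	MUT	7.275	>50	MUT	2.5
15	BL	WT	WT	WT	0.000				WT	WT	WT	0.191
16	BL	WT	WT	WT	0.115				WT	WT	WT	0.000
17	BL	WT	WT	WT	0.154				WT	WT	WT	0.264
18	BL	WT	WT	WT	0.101				WT	WT	WT	0.000
19	BL	WT	WT	WT	0.117		WT		WT	WT	MUT	0.815	>6	WT
20	BL	WT	WT	WT	0.097				WT	WT	WT	0.119
21	BL	WT	WT	WT	0.089				WT	WT	WT	0.308
22	BL	WT	WT	WT	0.000				WT	WT	MUT	0.644	6
23	BL	WT	WT	WT	0.000				WT	WT	WT	0.219
24	BL	WT	WT	WT	0.000				WT	WT	WT	0.000
25	BL	WT	WT	WT	0.000		nd		WT	WT	MUT	2.252	>12.5	nd
26	BL	WT	WT	WT	0.026				WT	WT	WT	0.000
27	BL	WT	WT	WT	0.000				WT	WT	WT	0.000
28	BL	WT	WT	WT	0.000		nd		WT	MUT	MUT	2.170	>12.5	nd
29	BL	WT	WT	WT	0.000				WT	WT	WT	0.285
31	BL	WT	WT	WT	0.095		WT		WT	WT	WT	0.383		WT
32	BL	WT	WT	WT	0.277		nd		WT	WT	WT	0.000		WT
33	BL	WT	WT	WT	0.000				WT	WT	WT	0.190
34	BL	WT	WT	WT	0.000				WT	WT	WT	0.000
51	BL	WT	nd	WT	0.000		nd		WT	nd	MUT	1.216	12.5	nd
53	BL	WT	nd	WT	0.258		nd		WT	nd	MUT	1.043	<12.5	nd
54	BL	WT	nd	WT	0.000		nd		WT	nd	WT	0.246		nd
30	BL	WT	nd	WT	0.000		nd		WT	nd	WT	0.171		nd
36	BL	WT	WT	WT	0.150				WT	WT	WT	0.202
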