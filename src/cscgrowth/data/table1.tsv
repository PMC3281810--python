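exp	phi21	phi31	phi41	phi54	phi61	phi71	phi81	label	csc_n	p_n	d_n
0	1	0.01	5.35	0.8	0.01	0.1	1	ss	0.0018	0.1875	0.8106
1	1.5	0.01	5.35	0.8	0.01	0.1	1	(-)		0.1878	0.8105
2	0.5	0.01	5.35	0.8	0.01	0.1	1	(+)		0.1871	0.8107
3	1	0.015	5.35	0.8	0.01	0.1	1	(-)		0.1874	0.8108
4	1	0.005	5.35	0.8	0.01	0.1	1	(+)		0.1875	0.8103
5	1	0.01	5.45	0.8	0.01	0.1	1	(-)		0.186	0.8128
6	1	0.01	5.25	0.8	0.01	0.1	1	(+)		0.1891	0.807
7	1	0.01	5.35	0.85	0.01	0.1	1	ss	0.0459	0.1703	0.7836
8	1	0.01	5.35	0.75	0.01	0.1	1	ss	0	0.218	0.7819
9	1	0.01	5.35	0.8	0.1	0.1	1	(-)		0.1871	0.8127
10	1	0.01	5.35	0.8	0.001	0.1	1	(+)		0.1876	0.81
11	1	0.01	5.35	0.8	0.01	1	1	ss	0.1435	0.1608	0.6955
12	1	0.01	5.35	0.8	0.01	0.01	1	(-)		0.194	0.8057
13	1	0.01	5.35	0.8	0.01	0.1	10	ss	0.0055	0.5588	0.4356
14	1	0.01	5.35	0.8	0.01	0.1	0.1	ss	0.0011	0.1119	0.8869
15	1.5	0.005	5.35	0.8	0.01	0.1	1	ss	0.0018	0.1878	0.8102
16	0.8	0.012	5.35	0.8	0.01	0.1	1	ss	0.0018	0.1873	0.8107
17	1.5	0.01	5.325	0.8	0.01	0.1	1	ss	0.0018	0.1882	0.8098
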