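residue	aa	atom	shift_ppm
1	G	HA2	4.101
1	G	HA3	3.923
2	F	HN	8.711
2	F	HA	4.421
2	F	HB2	3.240
2	F	HB3	3.075
2	F	HD	7.235
2	F	HE	7.321
3	L	HN	8.185
3	L	HA	4.059
3	L	HB2	1.683
3	L	HB3	1.569
3	L	HG	1.634
3	L	HD1	0.972
3	L	HD2	0.920
4	D	HN	7.573
4	D	HA	4.356
4	D	HB2	2.880
4	D	HB3	2.777
5	I	HN	7.482
5	I	HA	3.836
5	I	HB	2.064
5	I	HG12	1.251
5	I	HG2	0.917
5	I	HD1	0.922
6	I	HN	7.761
6	I	HA	3.731
6	I	HB	1.970
6	I	HG12	1.482
6	I	HG13	1.106
6	I	HG2	0.893
6	I	HD1	0.808
7	K	HN	8.246
7	K	HA	4.085
7	K	HB	1.939
7	K	HG2	1.666
7	K	HG3	1.486
7	K	HD	1.733
7	K	HE	2.980
8	D	HN	8.452
8	D	HA	4.603
8	D	HB2	3.075
8	D	HB3	2.941
9	T	HN	8.219
9	T	HA	4.351
9	T	HB	4.136
9	T	HG2	1.293
10	G	HN	8.254
10	G	HA	3.998
11	K	HN	7.971
11	K	HA	4.198
11	K	HB	2.005
11	K	HG2	1.655
11	K	HG3	1.525
11	K	HD	1.764
11	K	HE2	3.021
11	K	HE3	3.005
12	E	HN	8.070
12	E	HA	4.056
12	E	HB2	2.288
12	E	HB3	2.172
12	E	HG2	2.606
12	E	HG3	2.457
13	F	HN	8.226
13	F	HA	4.348
13	F	HB	3.272
13	F	HD1	7.277
13	F	HD2	7.291
14	A	HN	8.014
14	A	HA	4.035
14	A	HB	1.587
15	V	HN	8.039
15	V	HA	3.656
15	V	HB	2.222
15	V	HG1	1.125
15	V	HG2	0.989
16	K	HN	7.841
16	K	HA	4.059
16	K	HB2	2.058
16	K	HB3	1.964
16	K	HG2	1.478
16	K	HG3	1.449
16	K	HD2	1.716
16	K	HD3	1.676
16	K	HE2	3.007
16	K	HE3	2.994
17	I	HN	8.217
17	I	HA	3.732
17	I	HB	1.979
17	I	HG12	1.499
17	I	HG13	1.071
17	I	HG2	0.888
17	I	HD1	0.725
18	L	HN	8.561
18	L	HA	4.132
18	L	HB	1.925
18	L	HG	1.583
18	L	HD	0.922
19	N	HN	8.453
19	N	HA	4.477
19	N	HB2	2.972
19	N	HB3	2.771
19	N	HD21	6.588
20	N	HN	8.063
20	N	HA	4.521
20	N	HB2	3.051
20	N	HB3	2.831
20	N	HD21	6.789
21	L	HN	8.477
21	L	HA	4.134
21	L	HB2	1.919
21	L	HB3	1.844
21	L	HG	1.781
21	L	HD1	0.948
21	L	HD2	0.914
22	K	HN	8.395
22	K	HA	3.944
22	K	HB	2.003
22	K	HG	1.455
22	K	HD2	1.720
22	K	HD3	1.673
22	K	HE	2.978
23	C	HN	7.987
23	C	HA	4.328
23	C	HB2	3.472
23	C	HB3	3.185
24	K	HN	8.200
24	K	HA	4.185
24	K	HB2	2.091
24	K	HB3	1.988
24	K	HG2	1.645
24	K	HG3	1.517
24	K	HD	1.714
25	L	HN	8.476
25	L	HA	4.222
25	L	HB	1.892
25	L	HG	1.544
25	L	HD	0.906
26	A	HN	8.040
26	A	HA	4.471
26	A	HB	1.546
27	G	HN	7.791
27	G	HA2	4.304
27	G	HA3	3.936
28	G	HN	8.312
28	G	HA2	4.091
28	G	HA3	3.936
29	C	HN	8.012
29	C	HA	4.970
29	C	HB2	3.377
29	C	HB3	2.951
30	P	HA	4.662
30	P	HB2	2.324
30	P	HB3	2.064
30	P	HG	2.006
30	P	HD2	3.768
30	P	HD3	3.661
31	P	HA	4.391
31	P	HB2	2.313
31	P	HB3	2.058
31	P	HG	2.010
31	P	HD2	3.766
31	P	HD3	3.622
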