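# SYNTHETIC stand-in for the CFD mismatch penalty table: pairwise
# tolerances x linear positional decline toward the PAM; not the
# published empirical values.
pos	guide_base	genome_base	penalty
1	A	A	1.0
1	A	C	0.3
1	A	G	0.45
1	A	T	0.22
1	C	A	0.28
1	C	C	1.0
1	C	G	0.15
1	C	T	0.42
1	G	A	0.65
1	G	C	0.38
1	G	G	1.0
1	G	T	0.24
1	U	A	0.35
1	U	C	0.6
1	U	G	0.26
1	U	T	1.0
2	A	A	1.0
2	A	C	0.287368
2	A	G	0.431053
2	A	T	0.210737
2	C	A	0.268211
2	C	C	1.0
2	C	G	0.143684
2	C	T	0.402316
2	G	A	0.622632
2	G	C	0.364
2	G	G	1.0
2	G	T	0.229895
2	U	A	0.335263
2	U	C	0.574737
2	U	G	0.249053
2	U	T	1.0
3	A	A	1.0
3	A	C	0.274737
3	A	G	0.412105
3	A	T	0.201474
3	C	A	0.256421
3	C	C	1.0
3	C	G	0.137368
3	C	T	0.384632
3	G	A	0.595263
3	G	C	0.348
3	G	G	1.0
3	G	T	0.219789
3	U	A	0.320526
3	U	C	0.549474
3	U	G	0.238105
3	U	T	1.0
4	A	A	1.0
4	A	C	0.262105
4	A	G	0.393158
4	A	T	0.192211
4	C	A	0.244632
4	C	C	1.0
4	C	G	0.131053
4	C	T	0.366947
4	G	A	0.567895
4	G	C	0.332
4	G	G	1.0
4	G	T	0.209684
4	U	A	0.305789
4	U	C	0.524211
4	U	G	0.227158
4	U	T	1.0
5	A	A	1.0
5	A	C	0.249474
5	A	G	0.374211
5	A	T	0.182947
5	C	A	0.232842
5	C	C	1.0
5	C	G	0.124737
5	C	T	0.349263
5	G	A	0.540526
5	G	C	0.316
5	G	G	1.0
5	G	T	0.199579
5	U	A	0.291053
5	U	C	0.498947
5	U	G	0.216211
5	U	T	1.0
6	A	A	1.0
6	A	C	0.236842
6	A	G	0.355263
6	A	T	0.173684
6	C	A	0.221053
6	C	C	1.0
6	C	G	0.118421
6	C	T	0.331579
6	G	A	0.513158
6	G	C	0.3
6	G	G	1.0
6	G	T	0.189474
6	U	A	0.276316
6	U	C	0.473684
6	U	G	0.205263
6	U	T	1.0
7	A	A	1.0
7	A	C	0.224211
7	A	G	0.336316
7	A	T	0.164421
7	C	A	0.209263
7	C	C	1.0
7	C	G	0.112105
7	C	T	0.313895
7	G	A	0.485789
7	G	C	0.284
7	G	G	1.0
7	G	T	0.179368
7	U	A	0.261579
7	U	C	0.448421
7	U	G	0.194316
7	U	T	1.0
8	A	A	1.0
8	A	C	0.211579
8	A	G	0.317368
8	A	T	0.155158
8	C	A	0.197474
8	C	C	1.0
8	C	G	0.105789
8	C	T	0.296211
8	G	A	0.458421
8	G	C	0.268
8	G	G	1.0
8	G	T	0.169263
8	U	A	0.246842
8	U	C	0.423158
8	U	G	0.183368
8	U	T	1.0
9	A	A	1.0
9	A	C	0.198947
9	A	G	0.298421
9	A	T	0.145895
9	C	A	0.185684
9	C	C	1.0
9	C	G	0.099474
9	C	T	0.278526
9	G	A	0.431053
9	G	C	0.252
9	G	G	1.0
9	G	T	0.159158
9	U	A	0.232105
9	U	C	0.397895
9	U	G	0.172421
9	U	T	1.0
10	A	A	1.0
10	A	C	0.186316
10	A	G	0.279474
10	A	T	0.136632
10	C	A	0.173895
10	C	C	1.0
10	C	G	0.093158
10	C	T	0.260842
10	G	A	0.403684
10	G	C	0.236
10	G	G	1.0
10	G	T	0.149053
10	U	A	0.217368
10	U	C	0.372632
10	U	G	0.161474
10	U	T	1.0
11	A	A	1.0
11	A	C	0.173684
11	A	G	0.260526
11	A	T	0.127368
11	C	A	0.162105
11	C	C	1.0
11	C	G	0.086842
11	C	T	0.243158
11	G	A	0.376316
11	G	C	0.22
11	G	G	1.0
11	G	T	0.138947
11	U	A	0.202632
11	U	C	0.347368
11	U	G	0.150526
11	U	T	1.0
12	A	A	1.0
12	A	C	0.161053
12	A	G	0.241579
12	A	T	0.118105
12	C	A	0.150316
12	C	C	1.0
12	C	G	0.080526
12	C	T	0.225474
12	G	A	0.348947
12	G	C	0.204
12	G	G	1.0
12	G	T	0.128842
12	U	A	0.187895
12	U	C	0.322105
12	U	G	0.139579
12	U	T	1.0
13	A	A	1.0
13	A	C	0.148421
13	A	G	0.222632
13	A	T	0.108842
13	C	A	0.138526
13	C	C	1.0
13	C	G	0.074211
13	C	T	0.207789
13	G	A	0.321579
13	G	C	0.188
13	G	G	1.0
13	G	T	0.118737
13	U	A	0.173158
13	U	C	0.296842
13	U	G	0.128632
13	U	T	1.0
14	A	A	1.0
14	A	C	0.135789
14	A	G	0.203684
14	A	T	0.099579
14	C	A	0.126737
14	C	C	1.0
14	C	G	0.067895
14	C	T	0.190105
14	G	A	0.294211
14	G	C	0.172
14	G	G	1.0
14	G	T	0.108632
14	U	A	0.158421
14	U	C	0.271579
14	U	G	0.117684
14	U	T	1.0
15	A	A	1.0
15	A	C	0.123158
15	A	G	0.184737
15	A	T	0.090316
15	C	A	0.114947
15	C	C	1.0
15	C	G	0.061579
15	C	T	0.172421
15	G	A	0.266842
15	G	C	0.156
15	G	G	1.0
15	G	T	0.098526
15	U	A	0.143684
15	U	C	0.246316
15	U	G	0.106737
15	U	T	1.0
16	A	A	1.0
16	A	C	0.110526
16	A	G	0.165789
16	A	T	0.081053
16	C	A	0.103158
16	C	C	1.0
16	C	G	0.055263
16	C	T	0.154737
16	G	A	0.239474
16	G	C	0.14
16	G	G	1.0
16	G	T	0.088421
16	U	A	0.128947
16	U	C	0.221053
16	U	G	0.095789
16	U	T	1.0
17	A	A	1.0
17	A	C	0.097895
17	A	G	0.146842
17	A	T	0.071789
17	C	A	0.091368
17	C	C	1.0
17	C	G	0.048947
17	C	T	0.137053
17	G	A	0.212105
17	G	C	0.124
17	G	G	1.0
17	G	T	0.078316
17	U	A	0.114211
17	U	C	0.195789
17	U	G	0.084842
17	U	T	1.0
18	A	A	1.0
18	A	C	0.085263
18	A	G	0.127895
18	A	T	0.062526
18	C	A	0.079579
18	C	C	1.0
18	C	G	0.042632
18	C	T	0.119368
18	G	A	0.184737
18	G	C	0.108
18	G	G	1.0
18	G	T	0.068211
18	U	A	0.099474
18	U	C	0.170526
18	U	G	0.073895
18	U	T	1.0
19	A	A	1.0
19	A	C	0.072632
19	A	G	0.108947
19	A	T	0.053263
19	C	A	0.067789
19	C	C	1.0
19	C	G	0.036316
19	C	T	0.101684
19	G	A	0.157368
19	G	C	0.092
19	G	G	1.0
19	G	T	0.058105
19	U	A	0.084737
19	U	C	0.145263
19	U	G	0.062947
19	U	T	1.0
20	A	A	1.0
20	A	C	0.06
20	A	G	0.09
20	A	T	0.044
20	C	A	0.056
20	C	C	1.0
20	C	G	0.03
20	C	T	0.084
20	G	A	0.13
20	G	C	0.076
20	G	G	1.0
20	G	T	0.048
20	U	A	0.07
20	U	C	0.12
20	U	G	0.052
20	U	T	1.0
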