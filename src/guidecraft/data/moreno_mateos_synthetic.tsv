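# SYNTHETIC stand-in for the Moreno-Mateos-style identity-link
# position weight model; layout and link real, weights synthetic.
# name=moreno_mateos	window=6,6	link=identity
feature	weight
intercept	0.1839
A@10	-0.0147
A@11	0.0197
A@23	0.2137
A@25	0.1107
A@27	0.0723
A@29	-0.0196
A@30	-0.0732
A@31	0.0366
A@6	0.1516
A@7	0.0608
A@8	-0.0395
A@9	-0.0465
AA@14	-0.0492
AA@2	0.0753
AA@20	0.0337
AA@22	0.0383
AA@24	-0.0066
AA@4	0.0628
AC@15	-0.0068
AC@20	0.0316
AC@29	-0.1306
AG@12	-0.0065
AG@5	-0.0656
AG@9	-0.0261
AT@3	0.0669
C@12	0.1043
C@13	-0.0014
C@14	0.0251
C@18	-0.0359
C@19	-0.0054
C@24	-0.0412
C@25	-0.0788
C@27	0.073
C@29	-0.0485
C@32	0.2182
C@34	0.1249
C@35	-0.0957
C@8	0.0065
CA@1	-0.1129
CA@2	0.0635
CA@25	0.094
CA@8	-0.104
CC@24	-0.0448
CC@32	-0.0416
CG@20	0.0124
CT@13	0.0045
CT@32	0.0221
G@11	0.0169
G@15	0.1764
G@20	-0.1063
G@26	-0.1062
G@32	-0.071
G@6	0.0093
G@7	0.0408
GA@27	-0.0152
GC@14	0.0783
GG@1	0.069
GG@30	0.0305
GT@16	-0.0434
T@10	0.0809
T@12	0.1283
T@15	0.1669
T@16	0.0027
T@2	0.0913
T@21	-0.1314
T@23	-0.0133
T@25	-0.1466
T@27	0.1059
T@30	0.017
T@32	0.0089
T@33	-0.1025
T@8	-0.1363
TA@24	0.0142
TC@10	0.0759
TC@18	-0.0407
TC@34	-0.0151
TG@24	0.0112
TG@34	0.035
TG@4	0.0196
TT@11	-0.0201
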