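# SYNTHETIC stand-in for the Doench-2014-style logistic position
# weight model; feature layout and link real, weights synthetic.
# name=doench2014	window=4,3	link=logistic
feature	weight
intercept	0.5976
gc_low	-0.2026
gc_high	-0.1666
A@10	-0.1523
A@13	0.1249
A@14	-0.0672
A@16	0.0425
A@17	0.1432
A@18	-0.2375
A@21	-0.1323
A@28	0.0978
A@30	-0.0403
A@4	0.1852
A@7	-0.152
AA@19	0.076
AA@28	0.0742
AA@7	-0.0191
AC@22	0.0529
AC@23	-0.1345
AG@17	-0.0216
AG@27	0.0518
C@12	-0.0608
C@14	0.0664
C@16	-0.275
C@18	-0.1424
C@19	0.0961
C@25	-0.1928
C@28	-0.0745
C@7	-0.1182
CA@1	-0.033
CA@7	0.0934
CC@12	0.0007
CC@13	0.0731
CC@16	0.2241
CC@20	0.0799
CC@9	0.1076
CG@11	0.0002
CG@12	0.1365
CG@2	0.0748
CG@3	0.0131
CT@10	-0.1152
G@1	-0.0146
G@10	0.0953
G@11	0.0532
G@12	0.1282
G@13	-0.113
G@16	-0.0479
G@22	-0.0831
G@27	-0.0232
G@6	-0.135
G@9	-0.1685
GA@12	-0.0379
GC@7	0.0056
GG@12	-0.2517
GG@22	0.0549
GG@7	0.0299
T@13	-0.0686
T@19	-0.0262
T@22	0.0056
T@23	-0.0745
T@25	-0.1869
T@26	-0.1981
T@29	-0.0616
T@4	-0.2604
T@6	0.0262
T@7	-0.0572
T@9	0.1479
TA@16	-0.0395
TC@23	0.1887
TC@27	-0.0694
TC@6	-0.0833
TG@9	-0.1848
TT@27	-0.0677
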