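# CFD PAM penalties; canonical values keyed by the last two PAM bases,
# expanded over the (ignored) first base.
pam	penalty
AAA	0.000000000
AAC	0.000000000
AAG	0.259259259
AAT	0.000000000
ACA	0.000000000
ACC	0.000000000
ACG	0.107142857
ACT	0.000000000
AGA	0.069444444
AGC	0.022222222
AGG	1.000000000
AGT	0.016129032
ATA	0.000000000
ATC	0.000000000
ATG	0.038961039
ATT	0.000000000
CAA	0.000000000
CAC	0.000000000
CAG	0.259259259
CAT	0.000000000
CCA	0.000000000
CCC	0.000000000
CCG	0.107142857
CCT	0.000000000
CGA	0.069444444
CGC	0.022222222
CGG	1.000000000
CGT	0.016129032
CTA	0.000000000
CTC	0.000000000
CTG	0.038961039
CTT	0.000000000
GAA	0.000000000
GAC	0.000000000
GAG	0.259259259
GAT	0.000000000
GCA	0.000000000
GCC	0.000000000
GCG	0.107142857
GCT	0.000000000
GGA	0.069444444
GGC	0.022222222
GGG	1.000000000
GGT	0.016129032
GTA	0.000000000
GTC	0.000000000
GTG	0.038961039
GTT	0.000000000
TAA	0.000000000
TAC	0.000000000
TAG	0.259259259
TAT	0.000000000
TCA	0.000000000
TCC	0.000000000
TCG	0.107142857
TCT	0.000000000
TGA	0.069444444
TGC	0.022222222
TGG	1.000000000
TGT	0.016129032
TTA	0.000000000
TTC	0.000000000
TTG	0.038961039
TTT	0.000000000
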