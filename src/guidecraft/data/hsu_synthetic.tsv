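# SYNTHETIC stand-in for the normalized aggregate per-position
# mismatch cleavage frequencies (max over positions = 1).
pos	freq
1	1.0
2	0.95
3	0.9
4	0.85
5	0.8
6	0.75
7	0.7
8	0.65
9	0.6
10	0.55
11	0.5
12	0.45
13	0.4
14	0.35
15	0.3
16	0.25
17	0.2
18	0.15
19	0.1
20	0.05
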