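# SYNTHETIC stand-in for CROP-IT per-position cleavage weights:
# piecewise-constant over three PAM-anchored zones; values synthetic.
pos	weight
1	15
2	15
3	15
4	15
5	15
6	30
7	30
8	30
9	30
10	30
11	30
12	30
13	50
14	50
15	50
16	50
17	50
18	50
19	50
20	50
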