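# guidecraft

A Python toolkit for CRISPR/Cas9 guide RNA selection and for benchmarking
the prediction scores that selection relies on.

Choosing a guide RNA means trading off two sequence-determined properties:
**specificity** (how likely the Cas9–guide complex is to cut similar
sites elsewhere in the genome) and **on-target efficiency** (how well the
guide cuts its intended site). guidecraft provides both halves plus the
evaluation machinery to test how well the scores work:

* **Exhaustive off-target search** — every 23-nt window on either genome
  strand whose PAM matches an allowed pattern (NGG, plus the tolerated
  NAG/NGA) and whose 20-mer protospacer is within *k* Hamming mismatches
  of the guide (no indel/bulge alignment). Completeness is the contract:
  the scanner inspects every window, so it cannot miss a 4-mismatch site
  the way seed-limited heuristic aligners can, and a transparent naive
  scanner is kept as an independent oracle in the test suite.
* **Off-target scores** — the five standard per-site algorithms:

  - MIT: `100 · Π_{p∈MM}(1−w_p) · 1/(((19−d̄)/19)·4+1) · 1/n²`, with
    per-position weights `w_p`, mean pairwise mismatch distance `d̄`, and
    mismatch count `n`;
  - CFD: `Π_{p∈MM} penalty(p, guide base, genome base) · penalty(PAM)`;
  - CCTop: `Σ_{p∈MM} 1.2^p` (position 20 = PAM-proximal; rank ascending);
  - CROP-IT: sum of zone weights over *matched* positions;
  - Hsu: product of normalized per-position aggregate cleavage
    frequencies over mismatched positions.

* **Guide specificity score** — `100·100 / (100 + Σ hit scores)` over all
  floored off-target MIT hit scores (on-target excluded), range 0–100,
  higher = more specific; guides below 50 and guides with >75 % GC are
  flagged.
* **Efficiency models** — linear position-weight models over a sequence
  context window (logistic 30-mer Doench-2014-style, identity-link 35-mer
  Moreno-Mateos-style) plus the -GG terminal rule and last-4-bp GC count;
  model choice depends on whether guides are expressed from a U6 promoter
  or transcribed in vitro with T7.
* **Benchmarking** — validated off-target table cleaning (GC-outlier
  guides, modification-frequency floor), mismatch-depth histograms,
  tie-corrected ROC/AUC, score-cutoff TPR/FPR trade-offs, Spearman
  rank-correlation matrices with training-set flagging, top-quartile
  precision/recall, and two Monte-Carlo locus-resampling tests.
* **Synthetic data** — seeded generators for genomes with planted
  off-target sites (with a truth BED), validated off-target tables, and
  efficiency datasets with a tunable latent rank correlation (Gaussian
  copula), so everything is testable offline.

A note on constants: the MIT position weights and the CFD PAM penalties
ship as transcriptions of the widely reproduced canonical tables; the CFD
mismatch table, CROP-IT zone weights, Hsu frequency matrix, and the two
efficiency coefficient files are clearly labelled *synthetic* stand-ins
(`*_synthetic.tsv`) that follow the published structure with generated
values. All packaged tables are pinned by checksum in the test suite.

## Worked example

Design guides for a 323-bp region against a synthetic genome that
contains one deliberately promiscuous guide locus (25 planted near-match
sites):

```python
from guidecraft import fixtures as fx
from guidecraft.pipeline import design_region, RunConfig

genome, guides, records = fx.make_benchmark_study(seed=4)
region = genome["chr_bench_guide00"][21949:22272]
reports, hits = design_region(region, genome, RunConfig())
```

This prints (abridged):

```
42 guides designed, 19 off-target hits passed the floors
           guide   spec    mm0..mm4            flags doench2014
    guide_1_plus 100.00   0/0/0/0/0                -          -
    guide_7_plus 100.00   0/0/0/0/0                -      0.378
  guide_16_minus 100.00   0/0/0/0/0                -      0.564
...
  guide_150_plus  17.53   0/8/4/5/2  LOW_SPECIFICITY      0.405
```

Guides unique in the genome score a specificity of exactly 100 and rank
first; the planted promiscuous guide accumulates 19 floored off-targets
(8 with one mismatch), drops to specificity 17.5, and is flagged
`LOW_SPECIFICITY` (< 50). `guide_1_plus` sits too close to the region
edge for the 30-mer efficiency window, so its score is reported missing
rather than extrapolated.

The same workflow is available from the shell:

```sh
guidecraft design region.fa --genome genome.fa --out results/
guidecraft search GGTGAGTGAGTGTGTGCGTG --genome genome.fa --out hits.tsv
guidecraft bench-offtargets validated.tsv --genome genome.fa --out bench/
guidecraft bench-efficiency datasets.tsv --models doench2014 --out bench/
guidecraft simulate --what genome --seed 7 --out sim/
```

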