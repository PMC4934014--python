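# Methods

This note documents the models, conventions, numerical choices, and
limitations behind guidecraft. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

* **Coordinates** are 0-based, half-open (BED convention) everywhere in
  the library; 1-based numbers appear only in user-facing reports.
* **Protospacer positions** are numbered 1..20 with 1 = PAM-distal (5')
  and 20 = PAM-proximal. Every packaged constant table is stored in this
  convention and validated at load.
* **Guides** are exactly 20 nt with a 3-nt PAM immediately 3' (SpCas9
  geometry). 5'-PAM nucleases and other PAM lengths are out of scope.
* **Ambiguity**: genome windows whose protospacer or PAM contain N are
  excluded from guide discovery and off-target search — the scores are
  undefined on ambiguous bases. GC content is computed over the 20-mer
  protospacer only (not protospacer+PAM); that choice is a documented
  package convention.

## Off-target search

The search contract is **completeness**: return every 23-nt window on
either strand whose PAM matches one of the allowed patterns (default
NGG/NAG/NGA) and whose protospacer is within `max_mm` Hamming mismatches
of the guide. Alignment is strictly positional — no indels ("bulges") —
matching the dominant behaviour of validated off-target sites.

Two implementations share this contract. The production scanner encodes
the genome as a byte array and evaluates all windows in vectorized numpy
chunks (PAM filter first, then the mismatch count); one guide against a
10-Mb genome at `max_mm=4` takes a few seconds on one CPU. A pure-Python
per-window scanner with the identical contract is retained as the
independent oracle; property tests assert set equality between the two
on planted genomes. A seed-and-extend index was considered and rejected:
the vectorized full scan already meets the performance envelope and is
complete by construction rather than by analysis of a seeding scheme.

Defaults: `max_mm = 4` for guide ranking, 5 for deep single-guide
analysis. Overlapping sites on opposite strands are distinct hits. The
on-target locus is the 0-mismatch hit at the guide's anchor when an
anchor is provided; unanchored guides treat their single best 0-mismatch
hit (canonical NGG preferred, then deterministic genome order) as the
on-target. All other 0-mismatch hits are genuine off-targets.

## Off-target scores

All five scores are implemented from their defining formulas (see
README for the formulas). Choices worth recording:

* **MIT** single-mismatch convention: with fewer than two mismatches the
  mean pairwise distance d̄ is undefined, so both the proximity divisor
  and the count divisor are 1; a perfect match scores 100 exactly.
* **CCTop orientation**: the sum `Σ 1.2^p` grows when mismatches sit
  PAM-proximal, i.e. where they suppress cleavage most, so hits are
  ranked by *ascending* score for cleavage likelihood. This is fixed as
  the exported constant `CCTOP_ASCENDING_LIKELIHOOD`; ROC analyses
  negate the score so that "higher = more cleavage-likely" holds
  uniformly.
* **Hsu normalization**: the per-position aggregate frequencies are
  max-normalized (max over positions = 1); the loader rejects
  unnormalized matrices.
* **Score floors**: before specificity aggregation, hits are dropped
  when their MIT hit score falls strictly below their PAM's floor —
  0.1 for NGG and 1.0 for NAG/NGA with wild-type SpCas9. The VQR variant
  (NGA-preferring) swaps the profile: 0.1 for NAG, 1.0 for NGG/NGA.
  Floors are applied before the specificity sum, consistent with
  treating floored hits as ignored. Filtering is idempotent and
  subset-preserving; hits with a PAM matching no floor pattern are
  retained with a warning.
* **Precision**: scores are kept at full float precision internally and
  rounded to 4 decimals only in TSV reports.

### Packaged constant tables

The layout of each table (format, position convention, value ranges) is
enforced at load, and every shipped file is pinned by SHA-256 in the
test suite. Two files are transcriptions of the canonical, widely
reproduced constants: `mit_weights.tsv` (20 per-position weights) and
`cfd_pam.tsv` (PAM penalties keyed on the last two bases). The remaining
four — the 240-entry CFD mismatch table, the CROP-IT zone weights, the
Hsu frequency matrix, and the two efficiency coefficient files — are
**synthetic stand-ins**, generated by `scripts/generate_score_tables.py`
to follow the published qualitative structure (penalties declining
toward the PAM, wobble-like pairings most tolerated, three PAM-anchored
CROP-IT zones of 5/7/8 nt with weight rising toward the PAM, logistic
30-mer and identity 35-mer efficiency models). Their filenames carry the
`_synthetic` suffix and their headers say so. Formula correctness is
therefore established through hand-checkable toy tables in the unit
tests, never through the shipped numbers.

## Specificity and flags

`specificity = 100·100 / (100 + Σ mit_hit_score)` over the floored
off-target set, on-target excluded (passing the on-target is an error —
it would double-count the locus and every guide would self-penalize).
Zero off-targets give exactly 100. The score is strictly decreasing in
the off-target sum, and deepening the search can only lower it — the
stability property that justifies ranking at 4 mismatches.

Specificity aggregation uses MIT hit scores; a CFD-based aggregate with
the same functional form is exposed as `specificity_score_cfd` and
labelled as this package's own variant.

Flags use strict inequalities: `HIGH_GC` iff GC > 0.75 (a guide at
exactly 75 % is not flagged) and `LOW_SPECIFICITY` iff specificity < 50.
Both thresholds are parameters; workflows built on incomplete off-target
searches should raise the specificity demand to around 70–80, because a
search that misses sites inflates the score.

## Efficiency models

A model is `(features, window, link)`: intercept plus position-anchored
single-base (`B@p`) and dinucleotide (`BB@p`) indicator weights over a
context window (upstream flank + 20-mer + PAM + downstream flank), plus
protospacer GC-count terms (`gc_low`/`gc_high` weight each unit of GC
count below/above 10 of 20), optionally squashed by a logistic link.
Packaged: `doench2014` (logistic, 4+23+3 = 30-mer) and `moreno_mateos`
(identity, 6+23+6 = 35-mer), with synthetic weights as described above.
A context too short for a model's window yields a missing score, never
an extrapolation. Externally trained scores (Fusi/Azimuth, SVM-based
Wang/Xu and Chari, Wong, Housden) are supported only as precomputed
columns in benchmark tables; `recommend_model` maps U6-promoter
expression to the Fusi/Doench family (falling back to `doench2014` with
a notice when no external scorer is available) and T7 in vitro
transcription to `moreno_mateos`.

## Benchmarking

* **Cleaning**: drop the named GC-outlier guides (default `VEGFA_site2`,
  `HEK293_sgRNA4`), then keep records with modification frequency
  strictly above the floor. The floor is a parameter: 0.001 (0.1 %, the
  sensitivity of whole-genome cleavage assays) is the default, 1e-4 a
  documented alternative used by some analyses of the same data. The
  operation is idempotent and order-independent.
* **Candidate labeling**: the candidate universe is always regenerated
  by the package's own search (never read from an external prediction);
  a validated record whose site the search fails to produce goes into a
  `missed` sidecar rather than being silently dropped — this is exactly
  the failure mode that distinguishes complete from incomplete search
  tools.
* **ROC/AUC**: the AUC is the tie-corrected rank statistic
  (Mann-Whitney U / (n₊·n₋), ties counting 1/2), asserted equal to the
  O(n²) pairwise oracle to 1e-12 in tests; ROC point traces come from
  scikit-learn with intermediate points retained so every distinct
  cutoff appears. Cutoff analysis calls a site positive iff
  score ≥ cutoff.
* **Top-quartile precision/recall**: quartile size ⌈n/4⌉ with stable
  input-order tie-breaks; deterministic, no interpolation.
* **Locus resampling tests**: `best_of_locus_test` counts loci where the
  top-scored guide attains the locus's maximal activity and compares
  against drawing one guide uniformly per locus; `top_two_test` counts
  loci where the two top-scored guides include one of the top two
  measured activity values (tie-inclusive winner set) against two
  uniform draws without replacement. Both use a single seeded generator,
  100,000 draws by default, and report `p` as the fraction of null draws
  with at least the observed number of successes. Per-locus null success
  probabilities are exact (counting / hypergeometric), so the Monte-Carlo
  error is pure binomial sampling error; tests verify recovery of the
  closed-form p-values within 3 Monte-Carlo standard errors.

## Synthetic data

Generators are pure functions of (parameters, seed):

* `make_genome` draws an i.i.d. background (default uniform base
  composition; GC-skew option) and plants sites with exact mismatch
  patterns, PAMs, and strands, then re-scans its own output and aborts
  if the background happens to contain extra in-range sites (unless
  explicitly allowed). At megabase scale with `max_mm=4` such collisions
  are statistically expected, so large fixtures allow them and treat
  them as additional unvalidated candidates.
* `make_offtarget_table` emulates the layout of a multi-study validated
  off-target collection: per-guide site counts (1 + Poisson), mismatch
  counts drawn from a distribution putting ~88 % of mass at ≤ 4
  mismatches, log-uniform modification frequencies (so the cleaning
  floor removes a predictable share), optional GC-rich outlier guides,
  and optional per-guide normalization to sum 1 (emulating assays that
  observe only modification events).
* `make_benchmark_study` builds a complete evaluation: one chromosome
  per guide with an on-target plus planted 1–4-mismatch candidate sites;
  each site's latent cleavage frequency is a product of per-position
  tolerances declining *exponentially* toward the PAM times lognormal
  noise — deliberately a different functional form from any packaged
  score table, so the scores are evaluated against an independent ground
  truth. Sites above the frequency floor become validated records
  (roughly a third under defaults).
* `make_efficiency_dataset` couples score and activity through a
  Gaussian copula with Pearson parameter `2·sin(π·ρ_s/6)`, giving an
  exact population Spearman correlation; every downstream statistic is
  rank-based, so the Gaussian marginals are without loss of generality.

What passing tests on these fixtures shows: the algorithms implement
their definitions, the search is complete, the statistics recover known
parameters. What it does not show: performance on real genomes (repeats,
segmental duplications, chromatin effects) or the empirical accuracy of
the synthetic score tables against measured cleavage data.

## Problem sizes

The test suite verifies search completeness against the naive oracle on
a 1-Mb planted genome (the vectorized scanner itself is exercised at
10 Mb in a few seconds), rank-recovery at n = 50–1000, and resampling
tests at 100,000 draws. `scripts/acceptance.py` uses an 8-guide × 25-site
benchmark (~200 candidates), a 30-guide validated table, n = 200
efficiency datasets, and 100,000-draw locus tests; these sizes keep the
full reproduction under a few seconds while leaving all statistics
well-resolved.

## Known limitations

* No bulge (indel) off-target alignment, by design.
* Genomes are held in memory as strings; no index is built, so
  >100-Mb genomes are out of the intended envelope.
* Four of seven constant tables are synthetic stand-ins (see above);
  absolute score values from those tables should not be compared against
  published score values, though all structural and formula-level
  behaviour is faithful.
* The canonical specificity aggregate is MIT-based; the CFD variant
  is provided but not calibrated against any external reference.
* Efficiency models cover the linear position-weight family only;
  SVM-based and service-backed scores are import-only columns.
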