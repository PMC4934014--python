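"""Deterministic synthetic-data generators.

Everything here is a pure function of its parameters and seed, so every
other module can be tested with no downloads: genomes with planted
off-target sites of a specified mismatch pattern/PAM/strand, validated
off-target tables with per-guide frequency distributions, efficiency
datasets with a tunable true rank correlation (Gaussian copula), and
locus-grouped guide sets for the resampling tests.

What these emulate, and what they do not: the genome generator draws
background i.i.d. per base (default uniform 25 % each, optionally
GC-skewed), so it has no repeats, segmental duplications, or assembly
gaps; the off-target table emulates the *layout and marginals* of a
multi-study validated-site collection, not any real study's sites; the
copula generator controls only the rank dependence between score and
activity, with arbitrary marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bench import LocusDataset, LocusGuide, OffTargetRecord
from .otsearch import OffTargetHit, enumerate_offtargets
from .seqcore import (
    GUIDE_LEN,
    PAM_LEN,
    SITE_LEN,
    Genome,
    Guide,
    PamPattern,
    SPCAS9_OFFTARGET_PAMS,
    revcomp,
)

BASES = np.array(list("ACGT"))

#: Frequency floor the benchmark-study generator targets; matches the
#: default cleaning floor so roughly the intended share of planted sites
#: ends up validated.
DEFAULT_FREQ_FLOOR_HINT = 0.001


@dataclass(frozen=True)
class Plant:
    """One site to plant: its mismatch pattern, PAM, strand, position.

    ``mm_positions`` may be an explicit tuple (1..20 convention) or None
    to draw ``mm_count`` distinct positions at random. ``position`` is the
    0-based + strand start of the 23-nt site, or None for random placement.
    """

    mm_count: int
    mm_positions: Optional[tuple[int, ...]] = None
    pam: str = "AGG"
    strand: str = "+"
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.mm_count <= 6:
            raise ValueError("planted mm_count must be in 0..6")
        if self.mm_positions is not None and len(self.mm_positions) != self.mm_count:
            raise ValueError("mm_positions inconsistent with mm_count")


@dataclass
class PlantSpec:
    """Recipe for a synthetic genome with known planted off-target sites."""

    guide: Guide
    plants: Sequence[Plant]
    genome_len: int = 100_000
    chrom: str = "chrSim"
    gc_content: float = 0.5
    seed: int = 0
    allow_background_hits: bool = False


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one planted site (BED-compatible coordinates)."""

    chrom: str
    start: int  # 23-nt site start, + strand
    strand: str
    site_seq: str  # guide-oriented protospacer
    pam_seq: str
    mm_count: int
    mm_positions: tuple[int, ...]

    @property
    def end(self) -> int:
        return self.start + SITE_LEN

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


def _mutate(rng: np.random.Generator, proto: str, positions: Sequence[int]) -> str:
    seq = list(proto)
    for p in positions:
        choices = [b for b in "ACGT" if b != seq[p - 1]]
        seq[p - 1] = choices[rng.integers(0, 3)]
    return "".join(seq)


def make_genome(spec: PlantSpec) -> tuple[Genome, list[PlantedSite]]:
    """Generate a background genome and plant the requested sites.

    The background is drawn i.i.d. with the requested GC content; each
    plant is written with its exact mismatch pattern, PAM and strand. The
    generator then re-scans its own output and raises if the background
    accidentally contains additional sites within the planted mismatch
    range (unless ``allow_background_hits``); planted sites never overlap.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.genome_len < len(spec.plants) * SITE_LEN * 10:
        raise ValueError("genome too short for the requested number of plants")
    g = spec.gc_content / 2.0
    a = (1.0 - spec.gc_content) / 2.0
    seq = rng.choice(BASES, size=spec.genome_len, p=[a, g, g, a])

    # resolve plant positions, rejecting overlaps
    taken: list[tuple[int, int]] = []
    resolved: list[tuple[Plant, int, tuple[int, ...]]] = []
    for plant in spec.plants:
        if plant.position is not None:
            pos = plant.position
            if any(pos < e and pos + SITE_LEN > s for s, e in taken):
                raise ValueError(f"planted sites overlap at position {pos}")
        else:
            for _ in range(1000):
                pos = int(rng.integers(0, spec.genome_len - SITE_LEN + 1))
                if not any(pos < e and pos + SITE_LEN > s for s, e in taken):
                    break
            else:
                raise ValueError("could not place plant without overlap")
        taken.append((pos, pos + SITE_LEN))
        if plant.mm_positions is not None:
            mm_pos = tuple(sorted(plant.mm_positions))
        else:
            mm_pos = tuple(
                sorted(rng.choice(np.arange(1, GUIDE_LEN + 1), size=plant.mm_count,
                                  replace=False).tolist())
            )
        resolved.append((plant, pos, mm_pos))

    truth: list[PlantedSite] = []
    for plant, pos, mm_pos in resolved:
        site = _mutate(rng, spec.guide.protospacer, mm_pos)
        block = site + plant.pam.upper()
        if plant.strand == "-":
            block = revcomp(block)
        seq[pos : pos + SITE_LEN] = list(block)
        truth.append(
            PlantedSite(
                chrom=spec.chrom, start=pos, strand=plant.strand,
                site_seq=site, pam_seq=plant.pam.upper(),
                mm_count=len(mm_pos), mm_positions=mm_pos,
            )
        )
    genome = Genome({spec.chrom: "".join(seq)})

    if not spec.allow_background_hits:
        max_mm = max((p.mm_count for p in spec.plants), default=0)
        hits = enumerate_offtargets(spec.guide, genome, max_mm=max_mm,
                                    pams=SPCAS9_OFFTARGET_PAMS)
        truth_keys = {t.key() for t in truth}
        extras = [h for h in hits if h.key() not in truth_keys]
        if extras:
            raise ValueError(
                f"background contains {len(extras)} accidental sites within "
                f"{max_mm} mismatches (first at {extras[0].key()}); use a "
                "longer guide-distant background, another seed, or "
                "allow_background_hits=True"
            )
    truth.sort(key=lambda t: (t.chrom, t.start, 0 if t.strand == "+" else 1))
    return genome, truth


def truth_to_bed(truth: Sequence[PlantedSite]) -> str:
    """Truth sites as BED6 (name = mm count and positions)."""
    lines = [
        f"{t.chrom}\t{t.start}\t{t.end}\tmm{t.mm_count}:"
        f"{','.join(map(str, t.mm_positions)) or '-'}\t0\t{t.strand}"
        for t in truth
    ]
    return "\n".join(lines) + ("\n" if lines else "")


#: Mismatch-count distribution of validated off-targets used by
#: make_offtarget_table (counts 1..6): most validated sites carry at most
#: four mismatches (~88 % of the mass at <=4), a small tail at 5-6.
VALIDATED_MM_PROBS = (0.12, 0.22, 0.28, 0.26, 0.077, 0.043)


def _random_protospacer(rng: np.random.Generator, gc: float = 0.5) -> str:
    g = gc / 2.0
    a = (1.0 - gc) / 2.0
    return "".join(rng.choice(BASES, size=GUIDE_LEN, p=[a, g, g, a]))


def make_offtarget_table(
    n_guides: int = 20,
    mean_sites_per_guide: float = 8.0,
    freq_log10_range: tuple[float, float] = (-5.0, -0.3),
    outlier_fraction: float = 0.0,
    normalize_per_guide: bool = False,
    seed: int = 0,
) -> list[OffTargetRecord]:
    """Generate a validated off-target table in the benchmark layout.

    Per guide, 1 + Poisson(mean - 1) sites; per site, a mismatch count
    drawn from :data:`VALIDATED_MM_PROBS`, mutated positions uniform, and
    a modification frequency drawn log-uniform over ``freq_log10_range``
    (so a tunable share falls below any downstream frequency floor).
    ``outlier_fraction`` of guides are generated GC-rich (>75 %) and named
    with a ``gc_outlier_`` prefix so cleaning can target them.
    ``normalize_per_guide`` rescales each guide's frequencies to sum to 1,
    emulating assays that observe only modification events.
    """
    rng = np.random.default_rng(seed)
    n_outliers = math.ceil(outlier_fraction * n_guides)
    records: list[OffTargetRecord] = []
    for gi in range(n_guides):
        outlier = gi < n_outliers
        name = f"{'gc_outlier_' if outlier else ''}guide{gi:03d}"
        proto = _random_protospacer(rng, gc=0.85 if outlier else 0.5)
        n_sites = 1 + rng.poisson(max(mean_sites_per_guide - 1.0, 0.0))
        lo, hi = freq_log10_range
        freqs = 10.0 ** rng.uniform(lo, hi, size=n_sites)
        if normalize_per_guide:
            freqs = freqs / freqs.sum()
        for si in range(n_sites):
            mm = 1 + int(rng.choice(6, p=VALIDATED_MM_PROBS))
            mm_pos = sorted(
                rng.choice(np.arange(1, GUIDE_LEN + 1), size=mm, replace=False).tolist()
            )
            ot = _mutate(rng, proto, mm_pos)
            pam = "ACGT"[rng.integers(0, 4)] + ("GG" if rng.random() < 0.8 else "AG")
            records.append(
                OffTargetRecord(
                    study="sim", assay="sim",
                    guide_name=name, guide_seq=proto,
                    ot_seq=ot + pam, mm_count=mm,
                    modification_freq=float(freqs[si]),
                )
            )
    return records


#: Latent per-position mismatch tolerance of the benchmark-study cleavage
#: model: multiplicative, declining exponentially toward the PAM.
#: Deliberately a different functional form from any packaged score table
#: so that scores are evaluated against an independent ground truth.
def _latent_tolerance(p: int) -> float:
    return 0.85 * math.exp(-0.15 * p)

#: Overall scale of latent cleavage frequencies; with the tolerance above
#: and the default 0.1 % floor this leaves roughly a third of planted
#: sites validated, the rest as score-ranked negatives.
_LATENT_SCALE = 0.25


def make_benchmark_study(
    n_guides: int = 6,
    sites_per_guide: int = 25,
    chrom_len: int = 40_000,
    freq_floor: float = DEFAULT_FREQ_FLOOR_HINT,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> tuple[Genome, list[Guide], list[OffTargetRecord]]:
    """A self-contained validated-off-target benchmark.

    One chromosome per guide; each carries the guide's on-target site
    (0 mismatches, NGG) plus ``sites_per_guide`` planted candidate sites
    with 1-4 mismatches and PAMs from {NGG, NAG, NGA}. Each planted site
    receives a latent cleavage frequency: the product of per-position
    tolerances over its mismatches times lognormal noise. Sites whose
    frequency exceeds ``freq_floor`` become validated records, so the
    validated set is enriched for few, PAM-distal mismatches — the signal
    the off-target scores are supposed to recover. Background hits are
    tolerated (they become unvalidated candidates).
    """
    rng = np.random.default_rng(seed)
    guides: list[Guide] = []
    records: list[OffTargetRecord] = []
    sequences: dict[str, str] = {}
    pam_choices = ("AGG", "TGG", "CGG", "GGG", "AAG", "TGA")
    for gi in range(n_guides):
        name = f"bench_guide{gi:02d}"
        proto = _random_protospacer(rng)
        guide = Guide(name, proto, "AGG")
        plants = [Plant(mm_count=0, pam="AGG")]
        for _ in range(sites_per_guide):
            mm = int(rng.integers(1, 5))
            pam = pam_choices[rng.integers(0, len(pam_choices))]
            plants.append(Plant(mm_count=mm, pam=pam))
        chrom = f"chr_{name}"
        spec = PlantSpec(
            guide=guide, plants=plants, genome_len=chrom_len, chrom=chrom,
            seed=int(rng.integers(0, 2**31)), allow_background_hits=True,
        )
        sub_genome, truth = make_genome(spec)
        sequences[chrom] = sub_genome[chrom]
        guides.append(guide)
        for t in truth:
            if t.mm_count == 0:
                continue  # the on-target locus is not an off-target record
            lat = _LATENT_SCALE
            for p in t.mm_positions:
                lat *= _latent_tolerance(p)
            freq = min(lat * float(rng.lognormal(0.0, noise_sd)), 1.0)
            if freq > freq_floor:
                records.append(
                    OffTargetRecord(
                        study="sim", assay="sim", guide_name=name,
                        guide_seq=proto, ot_seq=t.site_seq + t.pam_seq,
                        mm_count=t.mm_count, modification_freq=freq,
                    )
                )
    return Genome(sequences), guides, records


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose copula has the
    given population Spearman correlation: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def make_efficiency_dataset(
    n: int = 100,
    latent_rho: float = 0.5,
    dataset: str = "sim",
    score_name: str = "score",
    seed: int = 0,
) -> pd.DataFrame:
    """(score, activity) pairs with population Spearman ``latent_rho``.

    A Gaussian copula couples the ranks; marginals are the Gaussians
    themselves (any monotone transform would leave every rank statistic
    unchanged). Columns: dataset, guide_id, seq, activity, <score_name>.
    """
    if not -1.0 <= latent_rho <= 1.0 or n < 4:
        raise ValueError("need |latent_rho| <= 1 and n >= 4")
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson(latent_rho)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    return pd.DataFrame(
        {
            "dataset": dataset,
            "guide_id": [f"g{i:04d}" for i in range(n)],
            "seq": [_random_protospacer(rng) for _ in range(n)],
            "activity": z[:, 0],
            score_name: z[:, 1],
        }
    )


def make_locus_dataset(
    n_loci: int = 8,
    guides_per_locus: int = 3,
    latent_rho: float = 0.7,
    model: str = "score",
    seed: int = 0,
) -> LocusDataset:
    """Locus-grouped guides with copula-coupled score and activity,
    for exercising the locus resampling tests."""
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson(latent_rho)
    cov = np.array([[1.0, r], [r, 1.0]])
    loci = {}
    for li in range(n_loci):
        z = rng.multivariate_normal([0.0, 0.0], cov, size=guides_per_locus,
                                    method="cholesky")
        loci[f"locus{li:02d}"] = [
            LocusGuide(
                guide_id=f"locus{li:02d}_g{gi}",
                activity=float(z[gi, 0]),
                scores={model: float(z[gi, 1])},
            )
            for gi in range(guides_per_locus)
        ]
    return LocusDataset(loci)
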