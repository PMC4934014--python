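import numpy as np
import pytest

from guidecraft import fixtures as fx
from guidecraft.otscore import CfdTables, CropItWeights, HsuMatrix, MitWeights, ScoreTables
from guidecraft.otsearch import OffTargetHit
from guidecraft.seqcore import Guide


def random_protospacer(seed: int) -> str:
    return fx._random_protospacer(np.random.default_rng(seed))


@pytest.fixture(scope="session")
def tables() -> ScoreTables:
    return ScoreTables.load()


@pytest.fixture(scope="session")
def toy_tables() -> ScoreTables:
    """Hand-checkable constant tables for formula tests."""
    mm = {
        (p, r, d): (1.0 if ("U" if d == "T" else d) == r else 0.5)
        for p in range(1, 21)
        for r in "ACGU"
        for d in "ACGT"
    }
    pam = {a + b + c: (1.0 if b + c == "GG" else 0.2)
           for a in "ACGT" for b in "ACGT" for c in "ACGT"}
    return ScoreTables(
        mit=MitWeights(tuple([0.0] * 20)),
        cfd=CfdTables(mm, pam),
        cropit=CropItWeights(tuple([1.0] * 20)),
        hsu=HsuMatrix(tuple(p / 20 for p in range(1, 21))),
    )


def hit_with(mm_positions, guide_seq="ACGTACGTACGTACGTACGT", pam="AGG",
             mutate_to=None) -> OffTargetHit:
    """Build a consistent hit by mutating the guide at the given positions."""
    site = list(guide_seq)
    for p in mm_positions:
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
        site[p - 1] = mutate_to or alt[site[p - 1]]
    return OffTargetHit(
        guide_name="g", chrom="chr1", start=100, strand="+",
        site_seq="".join(site), pam_seq=pam,
        mm_positions=tuple(sorted(mm_positions)),
    )


@pytest.fixture(scope="session")
def planted():
    """A small genome with 25 planted sites at 0-4 mismatches.

    Seed picked so the 60-kb background carries no accidental site within
    4 mismatches (the generator verifies this itself).
    """
    guide = Guide("planted_guide", random_protospacer(101))
    plants = [fx.Plant(mm_count=k % 5) for k in range(25)]
    genome, truth = fx.make_genome(
        fx.PlantSpec(guide, plants, genome_len=60_000, seed=101)
    )
    return guide, genome, truth


@pytest.fixture(scope="session")
def benchmark_study():
    return fx.make_benchmark_study(seed=4)
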