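"""Sequence-based off-target scoring: MIT, CFD, CCTop, CROP-IT, Hsu.

All five scores operate on a guide/site alignment (no indels) using the
package-wide position convention 1 = PAM-distal (5'), 20 = PAM-proximal.
Constant tables ship as TSV data files; files named ``*_synthetic.tsv``
contain structurally faithful but synthetic numeric stand-ins (see the
file headers), which is why unit tests pin files by checksum and exercise
the formulas through toy tables.

Score orientation: MIT, CFD, CROP-IT and Hsu are *descending-risk* scores
(higher = more cleavage-likely). CCTop is the opposite — see
:data:`CCTOP_ASCENDING_LIKELIHOOD`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from .otsearch import OffTargetHit
from .seqcore import GUIDE_LEN, Guide, PamPattern

logger = logging.getLogger(__name__)

#: CCTop sums 1.2**p over mismatch positions (p = 20 at the PAM-proximal
#: base), so a *larger* sum means mismatches sit where they suppress
#: cleavage most: hits are ranked by ASCENDING score when ordering by
#: cleavage likelihood. Fixed as a documented constant.
CCTOP_ASCENDING_LIKELIHOOD = True

CCTOP_BASE = 1.2


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("guidecraft").joinpath("data", name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop the column-header row


@dataclass(frozen=True)
class MitWeights:
    """MIT per-position mismatch penalty weights, index 1..20."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.w) != GUIDE_LEN or not all(0.0 <= x <= 1.0 for x in self.w):
            raise ValueError("MIT weights must be 20 values in [0, 1]")

    @classmethod
    def load(cls) -> "MitWeights":
        rows = _read_table("mit_weights.tsv")
        w = [0.0] * GUIDE_LEN
        for pos, weight in rows:
            w[int(pos) - 1] = float(weight)
        return cls(tuple(w))


@dataclass(frozen=True)
class CfdTables:
    """CFD penalty lookups: per-(position, guide RNA base, genome base) and per-PAM."""

    mm_penalty: Mapping[tuple[int, str, str], float]
    pam_penalty: Mapping[str, float]

    @classmethod
    def load(cls) -> "CfdTables":
        mm = {}
        for pos, rbase, dbase, pen in _read_table("cfd_mm_synthetic.tsv"):
            mm[(int(pos), rbase, dbase)] = float(pen)
        pam = {row[0]: float(row[1]) for row in _read_table("cfd_pam.tsv")}
        return cls(mm, pam)


@dataclass(frozen=True)
class CropItWeights:
    """CROP-IT per-position cleavage weights (piecewise over 3 PAM-anchored zones)."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.w) != GUIDE_LEN or any(x < 0 for x in self.w):
            raise ValueError("CROP-IT weights must be 20 non-negative values")
        if self.max_total <= 0:
            raise ValueError("CROP-IT weights must not be all zero")

    @property
    def max_total(self) -> float:
        return sum(self.w)

    @classmethod
    def load(cls) -> "CropItWeights":
        rows = _read_table("cropit_synthetic.tsv")
        w = [0.0] * GUIDE_LEN
        for pos, weight in rows:
            w[int(pos) - 1] = float(weight)
        return cls(tuple(w))


@dataclass(frozen=True)
class HsuMatrix:
    """Normalized aggregate per-position mismatch cleavage frequencies (max = 1)."""

    freq: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.freq) != GUIDE_LEN:
            raise ValueError("Hsu matrix must have 20 positions")
        if not all(0.0 < f <= 1.0 for f in self.freq):
            raise ValueError("Hsu frequencies must be in (0, 1]")
        if abs(max(self.freq) - 1.0) > 1e-9:
            raise ValueError("Hsu matrix must be max-normalized (max over positions = 1)")

    @classmethod
    def load(cls) -> "HsuMatrix":
        rows = _read_table("hsu_synthetic.tsv")
        f = [0.0] * GUIDE_LEN
        for pos, freq in rows:
            f[int(pos) - 1] = float(freq)
        return cls(tuple(f))


def _check_positions(positions: Iterable[int]) -> list[int]:
    pos = sorted(positions)
    if pos and (pos[0] < 1 or pos[-1] > GUIDE_LEN):
        raise ValueError(f"mismatch positions must be in 1..{GUIDE_LEN}, got {pos}")
    return pos


def mit_hit_score(
    guide_seq: str, hit: OffTargetHit, weights: Optional[MitWeights] = None
) -> float:
    """MIT per-off-target score in [0, 100].

    score = 100 x prod(1 - w[p]) x 1/(((19 - dbar)/19)*4 + 1) x 1/n^2
    where dbar is the mean pairwise distance (bp) between mismatch
    positions and n the mismatch count. Conventions: n = 0 gives 100;
    n = 1 sets both the proximity and the count divisor to 1.
    """
    if weights is None:
        weights = MitWeights.load()
    mm = _check_positions(hit.mm_positions)
    n = len(mm)
    score = 100.0
    for p in mm:
        score *= 1.0 - weights.w[p - 1]
    if n > 1:
        pairs = list(combinations(mm, 2))
        dbar = sum(abs(a - b) for a, b in pairs) / len(pairs)
        score *= 1.0 / (((19.0 - dbar) / 19.0) * 4.0 + 1.0)
        score *= 1.0 / (n * n)
    return score


def cfd_score(
    guide_seq: str, hit: OffTargetHit, tables: Optional[CfdTables] = None
) -> float:
    """Cutting Frequency Determination score in [0, 1].

    Product over mismatched positions of the (position, guide RNA base,
    genome base) penalty, times the PAM penalty. A perfect match with a
    canonical NGG PAM scores 1.0. Guide T is treated as RNA U for lookup.
    """
    if tables is None:
        tables = CfdTables.load()
    guide_rna = guide_seq.upper().replace("T", "U")
    site = hit.site_seq.upper()
    score = 1.0
    for p in _check_positions(hit.mm_positions):
        key = (p, guide_rna[p - 1], site[p - 1])
        if key not in tables.mm_penalty:
            raise KeyError(f"no CFD mismatch penalty for position/pair {key}")
        score *= tables.mm_penalty[key]
    pam = hit.pam_seq.upper()
    if pam not in tables.pam_penalty:
        raise KeyError(f"no CFD PAM penalty for {pam!r}")
    return score * tables.pam_penalty[pam]


def cctop_score(hit: OffTargetHit) -> float:
    """CCTop positional score: sum of 1.2**p over mismatch positions.

    p = 20 at the PAM-proximal base. 0 mismatches give 0. Rank by
    ascending score for cleavage likelihood (see
    :data:`CCTOP_ASCENDING_LIKELIHOOD`).
    """
    return float(sum(CCTOP_BASE ** p for p in _check_positions(hit.mm_positions)))


def cropit_score(hit: OffTargetHit, weights: Optional[CropItWeights] = None) -> float:
    """CROP-IT score: sum of position weights over MATCHED positions.

    A perfect match scores ``weights.max_total``; mismatches contribute 0.
    """
    if weights is None:
        weights = CropItWeights.load()
    mm = set(_check_positions(hit.mm_positions))
    return float(sum(w for p, w in enumerate(weights.w, start=1) if p not in mm))


def hsu_score(hit: OffTargetHit, matrix: Optional[HsuMatrix] = None) -> float:
    """Hsu score: product of normalized aggregate frequencies at mismatch positions."""
    if matrix is None:
        matrix = HsuMatrix.load()
    score = 1.0
    for p in _check_positions(hit.mm_positions):
        score *= matrix.freq[p - 1]
    return score


SCORE_NAMES = ("mit", "cfd", "cctop", "cropit", "hsu")

#: Scores where a LOWER value means more cleavage-likely.
ASCENDING_SCORES = frozenset({"cctop"}) if CCTOP_ASCENDING_LIKELIHOOD else frozenset()


@dataclass(frozen=True)
class ScoreTables:
    """Bundle of all constant tables, loaded once."""

    mit: MitWeights
    cfd: CfdTables
    cropit: CropItWeights
    hsu: HsuMatrix

    @classmethod
    def load(cls) -> "ScoreTables":
        return cls(MitWeights.load(), CfdTables.load(), CropItWeights.load(), HsuMatrix.load())


def score_hits(
    hits: Iterable[OffTargetHit],
    guide: Guide,
    tables: Optional[ScoreTables] = None,
) -> list[OffTargetHit]:
    """Fill ``hit.scores`` with all five algorithms for every hit, in place."""
    if tables is None:
        tables = ScoreTables.load()
    hits = list(hits)
    for h in hits:
        h.scores["mit"] = mit_hit_score(guide.protospacer, h, tables.mit)
        h.scores["cfd"] = cfd_score(guide.protospacer, h, tables.cfd)
        h.scores["cctop"] = cctop_score(h)
        h.scores["cropit"] = cropit_score(h, tables.cropit)
        h.scores["hsu"] = hsu_score(h, tables.hsu)
    return hits


#: Wild-type SpCas9 floors on the MIT hit score: hits strictly below their
#: PAM's floor are discarded before specificity aggregation.
SPCAS9_FLOORS: dict[PamPattern, float] = {
    PamPattern("NGG"): 0.1,
    PamPattern("NAG"): 1.0,
    PamPattern("NGA"): 1.0,
}

#: VQR SpCas9 variant (prefers NGA): NAG keeps the permissive floor,
#: NGG/NGA swap to the strict one.
VQR_FLOORS: dict[PamPattern, float] = {
    PamPattern("NAG"): 0.1,
    PamPattern("NGG"): 1.0,
    PamPattern("NGA"): 1.0,
}

FLOOR_PROFILES: dict[str, dict[PamPattern, float]] = {
    "spcas9": SPCAS9_FLOORS,
    "vqr": VQR_FLOORS,
    "none": {},
}


def apply_score_floors(
    hits: Iterable[OffTargetHit],
    floors: Optional[Mapping[PamPattern, float]] = None,
    score_name: str = "mit",
) -> list[OffTargetHit]:
    """Drop hits whose MIT hit score falls strictly below their PAM's floor.

    A hit whose PAM matches no floor key is retained with a warning. NGG is
    checked before the non-canonical patterns so that a PAM matching
    several keys takes the most specific floor. Idempotent; the output is
    always a subset of the input.
    """
    if floors is None:
        floors = SPCAS9_FLOORS
    # deterministic key order: exact-coded patterns first, NGG before NAG/NGA
    keys = sorted(floors, key=lambda p: (p.pattern.count("N"), p.pattern))
    out = []
    for h in hits:
        floor = None
        for pat in keys:
            if pat.matches(h.pam_seq):
                floor = floors[pat]
                break
        if floor is None:
            if floors:
                logger.warning(
                    "hit %s:%d PAM %s matches no floor pattern; retained",
                    h.chrom, h.start, h.pam_seq,
                )
            out.append(h)
        elif h.scores[score_name] >= floor:
            out.append(h)
    return out
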