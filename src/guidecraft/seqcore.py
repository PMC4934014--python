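"""Sequence and genome primitives shared by all other modules.

Conventions used package-wide:

* Coordinates are 0-based, half-open (BED convention). 1-based numbers
  appear only in user-facing reports.
* Guides are 20-nt protospacers read 5'→3' with a 3-nt PAM immediately 3'
  (SpCas9 geometry). Protospacer positions are numbered 1..20 with
  1 = PAM-distal (5' end) and 20 = PAM-proximal.
* Genome sequences are uppercase over the alphabet {A, C, G, T, N}; any
  other input character is mapped to N with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

GUIDE_LEN = 20
PAM_LEN = 3
SITE_LEN = GUIDE_LEN + PAM_LEN

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

#: IUPAC nucleotide codes -> set of concrete bases they match. A genome
#: base N matches nothing (scores are undefined on ambiguous bases).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PamPattern:
    """A 3-nt PAM pattern over IUPAC codes, e.g. NGG, NAG, NGA."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if len(pat) != PAM_LEN:
            raise ValueError(f"PAM pattern must be {PAM_LEN} nt, got {self.pattern!r}")
        for c in pat:
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC code {c!r} in PAM pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def matches(self, pam: str) -> bool:
        """True if the concrete 3-mer ``pam`` matches this pattern.

        A genome base N never matches, not even against pattern N.
        """
        if len(pam) != PAM_LEN:
            return False
        return all(b in IUPAC[p] for p, b in zip(self.pattern, pam.upper()))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.pattern


#: Default PAM set for SpCas9 off-target search.
SPCAS9_OFFTARGET_PAMS = (PamPattern("NGG"), PamPattern("NAG"), PamPattern("NGA"))


@dataclass(frozen=True)
class Guide:
    """A 20-nt protospacer with an observed PAM and optional genomic anchor.

    ``anchor`` is ``(sequence_name, start, strand)`` where ``start`` is the
    0-based position of the protospacer's 5'-most base on the + strand of
    the named sequence, in guide orientation.
    """

    name: str
    protospacer: str
    pam: str = ""
    anchor: Optional[tuple[str, int, str]] = None

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        if len(proto) != GUIDE_LEN or any(c not in "ACGT" for c in proto):
            raise ValueError(
                f"protospacer must be a {GUIDE_LEN}-mer over ACGT, got {self.protospacer!r}"
            )
        pam = self.pam.upper()
        if pam and (len(pam) != PAM_LEN or any(c not in "ACGT" for c in pam)):
            raise ValueError(f"PAM must be empty or a {PAM_LEN}-mer over ACGT, got {self.pam!r}")
        if self.anchor is not None and self.anchor[2] not in "+-":
            raise ValueError(f"anchor strand must be + or -, got {self.anchor[2]!r}")
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam", pam)


@dataclass
class Genome:
    """A named collection of uppercase nucleotide sequences."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def items(self) -> Iterable[tuple[str, str]]:
        return self.sequences.items()

    def slice(self, name: str, start: int, end: int, strand: str = "+") -> str:
        """Extract ``[start, end)`` from sequence ``name``; revcomp if strand is -."""
        seq = self.sequences[name][start:end]
        return revcomp(seq) if strand == "-" else seq


def _sanitize(seq: str, origin: str) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    bad = sorted(set(seq) - _VALID)
    logger.warning("record %s: mapping non-ACGTN characters %s to N", origin, bad)
    return "".join(c if c in _VALID else "N" for c in seq)


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Lowercase input is uppercased; characters outside {A,C,G,T,N} are
    mapped to N with a logged warning. An empty file or a duplicate record
    name is an error.
    """
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome.sequences:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        genome.sequences[rec.id] = _sanitize(str(rec.seq), rec.id)
    if not genome.sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    """Write a :class:`Genome` as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    s = seq.upper()
    if not set(s) <= _VALID:
        raise ValueError(f"cannot reverse-complement non-ACGTN sequence {seq!r}")
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length of an ACGT-only sequence.

    GC content is defined on unambiguous sequence (typically the 20-mer
    protospacer); N is an error, as is an empty string.
    """
    s = seq.upper()
    if not s:
        raise ValueError("gc_fraction of empty sequence is undefined")
    if any(c not in "ACGT" for c in s):
        raise ValueError(f"gc_fraction requires ACGT only, got {seq!r}")
    return (s.count("G") + s.count("C")) / len(s)


def _iter_pam_sites(region: str, pam: PamPattern) -> Iterator[int]:
    """Yield 0-based start positions of 23-nt guide sites on the given strand."""
    for start in range(0, len(region) - SITE_LEN + 1):
        proto = region[start : start + GUIDE_LEN]
        pam_seq = region[start + GUIDE_LEN : start + SITE_LEN]
        if "N" in proto or "N" in pam_seq:
            continue
        if pam.matches(pam_seq):
            yield start


def find_guides(region: str, pam: PamPattern = PamPattern("NGG"), name_prefix: str = "guide") -> list[Guide]:
    """Find every 20-mer immediately 5' of a PAM match, on both strands.

    Guides are reported in guide orientation and anchored so that
    ``Genome.slice(name, start, start + 20, strand)`` reproduces the
    protospacer: the anchor start is the 0-based leftmost + strand position
    of the protospacer's 20-bp span. Order is deterministic: ascending
    position of the 23-nt site, + before - at equal position.
    Windows containing N are skipped, not errors.
    """
    region = _sanitize(region, "region")
    if len(region) < SITE_LEN:
        raise ValueError(f"region must be at least {SITE_LEN} nt, got {len(region)}")
    rc = revcomp(region)
    n = len(region)
    found: list[tuple[int, str, Guide]] = []
    for start in _iter_pam_sites(region, pam):
        g = Guide(
            name=f"{name_prefix}_{start}_plus",
            protospacer=region[start : start + GUIDE_LEN],
            pam=region[start + GUIDE_LEN : start + SITE_LEN],
            anchor=("region", start, "+"),
        )
        found.append((start, "+", g))
    for rc_start in _iter_pam_sites(rc, pam):
        # site occupies [n - rc_start - SITE_LEN, n - rc_start) on +; the
        # protospacer 20-mer is the rightmost 20 nt of that window.
        site_start = n - rc_start - SITE_LEN
        g = Guide(
            name=f"{name_prefix}_{site_start}_minus",
            protospacer=rc[rc_start : rc_start + GUIDE_LEN],
            pam=rc[rc_start + GUIDE_LEN : rc_start + SITE_LEN],
            anchor=("region", site_start + PAM_LEN, "-"),
        )
        found.append((site_start, "-", g))
    found.sort(key=lambda t: (t[0], 0 if t[1] == "+" else 1))
    return [g for _, _, g in found]


def guides_to_bed(guides: Iterable[Guide], chrom: str = "region") -> str:
    """Render guides as BED6 text (protospacer interval, score column 0)."""
    lines = []
    for g in guides:
        if g.anchor is None:
            continue
        name, start, strand = g.anchor
        if strand == "+":
            lines.append(f"{chrom}\t{start}\t{start + GUIDE_LEN}\t{g.name}\t0\t+")
        else:
            lines.append(f"{chrom}\t{start}\t{start + GUIDE_LEN}\t{g.name}\t0\t-")
    return "\n".join(lines) + ("\n" if lines else "")
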