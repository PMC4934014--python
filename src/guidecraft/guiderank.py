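"""Per-guide specificity aggregation, quality flags, and ranking.

The guide specificity score summarizes all of a guide's predicted
off-targets into one number in [0, 100] (100 = best):

    specificity = 100 * 100 / (100 + sum of MIT hit scores)

with the guide's own on-target locus excluded from the sum. High-GC
guides (>75 % GC over the 20-mer) and low-specificity guides (<50) are
flagged; both thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .otsearch import OffTargetHit
from .seqcore import Guide, gc_fraction


class GuideFlag(str, Enum):
    HIGH_GC = "HIGH_GC"
    LOW_SPECIFICITY = "LOW_SPECIFICITY"


#: Minimum specificity highlighted as acceptable for exhaustive searches;
#: workflows relying on incomplete off-target searches should demand more
#: (around 70-80).
DEFAULT_SPECIFICITY_THRESHOLD = 50.0
DEFAULT_GC_THRESHOLD = 0.75


@dataclass
class GuideReport:
    guide: Guide
    specificity: float
    offtarget_counts: dict[int, int] = field(default_factory=dict)
    flags: frozenset[GuideFlag] = frozenset()
    efficiency: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def total_offtargets(self) -> int:
        return sum(self.offtarget_counts.values())


def specificity_score(
    hits: Sequence[OffTargetHit], on_target: Optional[OffTargetHit] = None
) -> float:
    """Aggregate floored MIT hit scores into the guide specificity score.

    ``hits`` must already be scored with the MIT hit score and floored and
    must NOT contain the on-target (that would double count it); pass the
    anchored 0-mismatch hit as ``on_target`` so the error can be raised.
    Zero off-targets give exactly 100.
    """
    if on_target is not None and any(h is on_target or h.key() == on_target.key() for h in hits):
        raise ValueError("on-target hit must be excluded from the specificity sum")
    total = sum(h.scores["mit"] for h in hits)
    return 100.0 * 100.0 / (100.0 + total)


def specificity_score_cfd(
    hits: Sequence[OffTargetHit], on_target: Optional[OffTargetHit] = None
) -> float:
    """CFD-aggregated specificity variant (0-100), same functional form.

    CFD hit scores lie in [0, 1] and are rescaled by 100 before the sum.
    This aggregate is this package's own variant; the canonical guide
    specificity score is the MIT-based :func:`specificity_score`.
    """
    if on_target is not None and any(h is on_target or h.key() == on_target.key() for h in hits):
        raise ValueError("on-target hit must be excluded from the specificity sum")
    total = sum(100.0 * h.scores["cfd"] for h in hits)
    return 100.0 * 100.0 / (100.0 + total)


def flag_guide(
    guide: Guide,
    specificity: float,
    gc_threshold: float = DEFAULT_GC_THRESHOLD,
    specificity_threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
) -> frozenset[GuideFlag]:
    """HIGH_GC iff GC(protospacer) > gc_threshold (strict); LOW_SPECIFICITY
    iff specificity < specificity_threshold (strict)."""
    flags = set()
    if gc_fraction(guide.protospacer) > gc_threshold:
        flags.add(GuideFlag.HIGH_GC)
    if specificity < specificity_threshold:
        flags.add(GuideFlag.LOW_SPECIFICITY)
    return frozenset(flags)


def rank_guides(reports: Iterable[GuideReport]) -> list[GuideReport]:
    """Order reports by descending specificity; ties by ascending total
    off-target count, then by anchor position. Stable and deterministic."""
    def _pos(r: GuideReport) -> tuple:
        a = r.guide.anchor
        return (a[0], a[1], a[2]) if a is not None else ("", -1, "")

    return sorted(
        reports, key=lambda r: (-r.specificity, r.total_offtargets, _pos(r))
    )


REPORT_COLUMNS = (
    "guide", "sequence", "pam", "chrom", "start", "strand",
    "specificity", "mm0", "mm1", "mm2", "mm3", "mm4", "flags",
)


def reports_to_tsv(reports: Iterable[GuideReport], efficiency_models: Sequence[str] = ()) -> str:
    """Fixed-column guide report TSV (positions 0-based; scores at 4 decimals)."""
    lines = ["\t".join(REPORT_COLUMNS + tuple(efficiency_models))]
    for r in reports:
        a = r.guide.anchor or ("", "", "")
        row = [
            r.guide.name, r.guide.protospacer, r.guide.pam,
            str(a[0]), str(a[1]), str(a[2]),
            f"{r.specificity:.4f}",
        ]
        row += [str(r.offtarget_counts.get(k, 0)) for k in range(5)]
        row.append(",".join(sorted(f.value for f in r.flags)))
        for m in efficiency_models:
            v = r.efficiency.get(m)
            row.append("" if v is None else f"{v:.4f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
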