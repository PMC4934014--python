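"""End-to-end guide design: discovery, off-target search, scoring, ranking.

This is the library form of the ``design`` command: find candidate guides
in a target region, enumerate and score their genome-wide off-targets,
apply the PAM score floors, aggregate specificity, flag and rank, and
attach on-target efficiency predictions where the region provides enough
flanking sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import efficiency as eff
from .guiderank import (
    DEFAULT_GC_THRESHOLD,
    DEFAULT_SPECIFICITY_THRESHOLD,
    GuideReport,
    flag_guide,
    rank_guides,
    specificity_score,
)
from .otscore import FLOOR_PROFILES, ScoreTables, apply_score_floors, score_hits
from .otsearch import (
    DEFAULT_MAX_MM,
    OffTargetHit,
    enumerate_offtargets,
    split_on_target,
)
from .seqcore import (
    GUIDE_LEN,
    Genome,
    Guide,
    PamPattern,
    SPCAS9_OFFTARGET_PAMS,
    find_guides,
    revcomp,
)


@dataclass
class RunConfig:
    """Knobs of a design/benchmark run; echoed into every output."""

    pam: str = "NGG"
    offtarget_pams: tuple[str, ...] = tuple(p.pattern for p in SPCAS9_OFFTARGET_PAMS)
    max_mm: int = DEFAULT_MAX_MM
    floors_profile: str = "spcas9"
    freq_floor: float = 0.001
    specificity_threshold: float = DEFAULT_SPECIFICITY_THRESHOLD
    gc_threshold: float = DEFAULT_GC_THRESHOLD
    efficiency_models: tuple[str, ...] = ("doench2014", "moreno_mateos")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.floors_profile not in FLOOR_PROFILES:
            raise ValueError(
                f"floors profile must be one of {sorted(FLOOR_PROFILES)}"
            )
        if not 0 <= self.max_mm <= 6:
            raise ValueError("max_mm must be in 0..6")
        if not 0 <= self.specificity_threshold <= 100:
            raise ValueError("specificity threshold must be in [0, 100]")
        if not 0 <= self.gc_threshold <= 1:
            raise ValueError("gc threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "pam": self.pam,
            "offtarget_pams": list(self.offtarget_pams),
            "max_mm": self.max_mm,
            "floors_profile": self.floors_profile,
            "freq_floor": self.freq_floor,
            "specificity_threshold": self.specificity_threshold,
            "gc_threshold": self.gc_threshold,
            "efficiency_models": list(self.efficiency_models),
            "seed": self.seed,
        }


def context_for_guide(region: str, guide: Guide) -> Optional[eff.GuideContext]:
    """Sequence context for efficiency scoring, oriented with the guide.

    Returns None when the region contains ambiguous bases in the window
    of interest; models themselves report missing scores when the flank
    is too short.
    """
    if guide.anchor is None:
        return None
    _, start, strand = guide.anchor
    if strand == "+":
        seq, offset = region, start
    else:
        seq, offset = revcomp(region), len(region) - start - GUIDE_LEN
    # trim to the widest packaged-model window so a distant ambiguous base
    # does not invalidate the context; a short flank stays short and the
    # model reports the score as missing
    max_flank = 6
    lo = max(0, offset - max_flank)
    hi = min(len(seq), offset + GUIDE_LEN + 3 + max_flank)
    try:
        return eff.GuideContext(seq[lo:hi], offset - lo)
    except ValueError:
        return None


def design_region(
    region: str,
    genome: Genome,
    config: Optional[RunConfig] = None,
    tables: Optional[ScoreTables] = None,
) -> tuple[list[GuideReport], list[OffTargetHit]]:
    """Run the full design workflow on one target region.

    Guides are discovered in ``region`` with the configured design PAM and
    searched against ``genome`` with the off-target PAM set. Each guide's
    best perfect-match genomic hit is treated as its on-target locus and
    excluded from the specificity sum. Returns ranked reports and all
    floored off-target hits.
    """
    config = config or RunConfig()
    tables = tables or ScoreTables.load()
    guides = find_guides(region, PamPattern(config.pam))
    pams = tuple(PamPattern(p) for p in config.offtarget_pams)
    floors = FLOOR_PROFILES[config.floors_profile]
    models = [eff.EfficiencyModel.load(m) for m in config.efficiency_models]

    reports: list[GuideReport] = []
    all_hits: list[OffTargetHit] = []
    for g in guides:
        search_guide = Guide(g.name, g.protospacer, g.pam)  # unanchored search
        hits = enumerate_offtargets(search_guide, genome, config.max_mm, pams)
        score_hits(hits, g, tables)
        on_target, off = split_on_target(hits, search_guide)
        off = apply_score_floors(off, floors)
        spec = specificity_score(off, on_target)
        counts = {k: 0 for k in range(config.max_mm + 1)}
        for h in off:
            counts[h.mm_count] += 1
        ctx = context_for_guide(region, g)
        effs = {
            m.name: (eff.score_guide_context(m, ctx) if ctx is not None else None)
            for m in models
        }
        reports.append(
            GuideReport(
                guide=g,
                specificity=spec,
                offtarget_counts=counts,
                flags=flag_guide(g, spec, config.gc_threshold,
                                 config.specificity_threshold),
                efficiency=effs,
            )
        )
        all_hits.extend(off)
    return rank_guides(reports), all_hits
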