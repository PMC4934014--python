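"""On-target efficiency heuristics and linear position-weight scoring models.

A model is a table of (feature, weight) pairs evaluated over a sequence
context window around the 23-nt protospacer+PAM, summed and optionally
passed through a logistic link. Feature keys:

* ``B@p``  — single base B at 1-based context position p
* ``BB@p`` — dinucleotide BB starting at context position p
* ``gc_low`` / ``gc_high`` — per-unit deviation of the protospacer GC
  count below/above 10 (of 20)
* ``intercept`` — always applied

Two packaged models are provided: ``doench2014`` (logistic link, 30-mer
window: 4 nt upstream + 20 + PAM + 3 nt downstream) and ``moreno_mateos``
(identity link, 35-mer window: 6 nt up + 20 + PAM + 6 nt down). Their
coefficient files are synthetic stand-ins — structurally faithful
(window, link, feature syntax) but with generated weights; see the data
file headers. Model choice by expression system: U6-promoter expression
is best served by the Fusi/Doench family, T7 in vitro transcription by
the Moreno-Mateos family; the -GG terminal dinucleotide rule and the GC
count of the last four protospacer bases are the two quick heuristics for
T7-transcribed guides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

from .seqcore import GUIDE_LEN, PAM_LEN, Guide

logger = logging.getLogger(__name__)

PACKAGED_MODELS = {
    "doench2014": "doench2014_synthetic.tsv",
    "moreno_mateos": "moreno_mateos_synthetic.tsv",
}

#: Models representable only as precomputed score columns (external
#: trained models / services); never computed by this package.
EXTERNAL_MODELS = ("fusi_doench", "wang_xu", "chari", "wong", "housden")


@dataclass(frozen=True)
class GuideContext:
    """A sequence window around the protospacer+PAM for model evaluation.

    ``offset`` is the 0-based position of the protospacer's first base
    within ``seq``.
    """

    seq: str
    offset: int

    def __post_init__(self) -> None:
        s = self.seq.upper()
        if any(c not in "ACGT" for c in s):
            raise ValueError("context must be ACGT only")
        if not 0 <= self.offset <= len(s) - GUIDE_LEN - PAM_LEN:
            raise ValueError("protospacer+PAM must fit inside the context window")
        object.__setattr__(self, "seq", s)

    @property
    def protospacer(self) -> str:
        return self.seq[self.offset : self.offset + GUIDE_LEN]


@dataclass(frozen=True)
class EfficiencyModel:
    """A linear position-weight efficiency model."""

    name: str
    upstream: int
    downstream: int
    features: Mapping[str, float]
    link: str = "identity"

    def __post_init__(self) -> None:
        if self.link not in ("identity", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")
        if "intercept" not in self.features:
            raise ValueError("model must define an intercept")
        for key in self.features:
            self._check_key(key)

    @property
    def window(self) -> int:
        return self.upstream + GUIDE_LEN + PAM_LEN + self.downstream

    def _check_key(self, key: str) -> None:
        if key in ("intercept", "gc_low", "gc_high"):
            return
        mer, _, pos = key.partition("@")
        if not pos.isdigit() or len(mer) not in (1, 2) or any(c not in "ACGT" for c in mer):
            raise ValueError(f"malformed feature key {key!r}")
        if int(pos) < 1 or int(pos) + len(mer) - 1 > self.window:
            raise ValueError(
                f"feature {key!r} outside the {self.window}-nt context window"
            )

    @classmethod
    def load(cls, name: str) -> "EfficiencyModel":
        """Load a packaged model by name (see :data:`PACKAGED_MODELS`)."""
        if name not in PACKAGED_MODELS:
            raise KeyError(
                f"unknown packaged model {name!r}; available: {sorted(PACKAGED_MODELS)}"
            )
        text = resources.files("guidecraft").joinpath(
            "data", PACKAGED_MODELS[name]).read_text()
        meta: dict[str, str] = {}
        features: dict[str, float] = {}
        for line in text.splitlines():
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, _, v = tok.partition("=")
                        meta[k] = v
                continue
            if not line or line == "feature\tweight":
                continue
            key, _, w = line.partition("\t")
            features[key] = float(w)
        up, down = (int(x) for x in meta["window"].split(","))
        return cls(meta["name"], up, down, features, meta["link"])


def score_linear(model: EfficiencyModel, ctx: GuideContext) -> float:
    """Evaluate a linear model on a context window.

    The model's window is aligned so that the protospacer starts at
    window position ``model.upstream + 1``; the context must provide at
    least that much flank on both sides.
    """
    start = ctx.offset - model.upstream
    end = ctx.offset + GUIDE_LEN + PAM_LEN + model.downstream
    if start < 0 or end > len(ctx.seq):
        raise ValueError(
            f"model {model.name!r} needs a {model.window}-nt window "
            f"({model.upstream} nt upstream, {model.downstream} nt downstream "
            f"of the 23-nt site); context provides [{ctx.offset} nt, "
            f"{len(ctx.seq) - ctx.offset - GUIDE_LEN - PAM_LEN} nt]"
        )
    window = ctx.seq[start:end]
    s = model.features["intercept"]
    gc = ctx.protospacer.count("G") + ctx.protospacer.count("C")
    if gc < 10 and "gc_low" in model.features:
        s += model.features["gc_low"] * (10 - gc)
    if gc > 10 and "gc_high" in model.features:
        s += model.features["gc_high"] * (gc - 10)
    for key, w in model.features.items():
        if key in ("intercept", "gc_low", "gc_high"):
            continue
        mer, _, pos = key.partition("@")
        p = int(pos) - 1
        if window[p : p + len(mer)] == mer:
            s += w
    if model.link == "logistic":
        return 1.0 / (1.0 + math.exp(-s))
    return s


def score_guide_context(
    model: EfficiencyModel, ctx: GuideContext
) -> Optional[float]:
    """Like :func:`score_linear` but returns None when the window is short.

    Degenerate contexts (region edge, insufficient flank) yield a missing
    score, never an extrapolated one.
    """
    try:
        return score_linear(model, ctx)
    except ValueError:
        return None


def gg_rule(guide: Guide) -> bool:
    """True iff the protospacer ends in -GG (positions 19-20)."""
    return guide.protospacer.endswith("GG")


def gc_last4(guide: Guide) -> int:
    """GC count of the last four protospacer bases (positions 17-20)."""
    tail = guide.protospacer[GUIDE_LEN - 4 :]
    return tail.count("G") + tail.count("C")


def recommend_model(
    expression: str, available: Optional[set[str]] = None
) -> str:
    """Recommend the efficiency model for an expression system.

    ``u6_promoter`` (plasmid/lentiviral expression in cells) maps to the
    Fusi/Doench score, falling back to ``doench2014`` with a logged notice
    when no external Fusi scorer is available; ``t7_invitro`` (in vitro
    transcription, e.g. zebrafish or mouse zygote injection) maps to
    ``moreno_mateos``.
    """
    valid = ("u6_promoter", "t7_invitro")
    if expression == "u6_promoter":
        if available is not None and "fusi_doench" not in available:
            logger.info(
                "fusi_doench scorer not available; falling back to doench2014"
            )
            return "doench2014"
        return "fusi_doench"
    if expression == "t7_invitro":
        return "moreno_mateos"
    raise ValueError(f"unknown expression system {expression!r}; valid: {valid}")
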