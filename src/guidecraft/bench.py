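"""Benchmarking machinery for off-target and efficiency predictions.

Covers the full evaluation workflow: ingestion and cleaning of validated
off-target tables, mismatch-depth summaries, labeling of candidate sites,
tie-corrected ROC/AUC and cutoff analysis, Spearman rank-correlation
matrices across efficiency datasets and models, top-quartile
precision/recall, and two Monte-Carlo locus-resampling tests that ask
whether picking guides by score beats picking them at random.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .otsearch import OffTargetHit, count_mismatches
from .seqcore import GUIDE_LEN

logger = logging.getLogger(__name__)

#: Guides dropped by default during cleaning: the two extreme-GC outliers
#: responsible for a large share of high-mismatch off-targets.
DEFAULT_GC_OUTLIER_GUIDES = ("VEGFA_site2", "HEK293_sgRNA4")

#: Default modification-frequency floor (fraction): keep > 0.1 %, the
#: sensitivity limit of whole-genome cleavage assays. An alternative floor
#: of 1e-4 (0.01 %) is sometimes quoted for the same cleaning step; the
#: floor is therefore a parameter, not a constant.
DEFAULT_FREQ_FLOOR = 0.001


@dataclass(frozen=True)
class OffTargetRecord:
    """One row of a validated off-target benchmark table."""

    study: str
    assay: str
    guide_name: str
    guide_seq: str
    ot_seq: str  # 20-mer protospacer + 3-nt PAM
    mm_count: int
    modification_freq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.modification_freq <= 1.0:
            raise ValueError(
                f"modification frequency must be in [0, 1], got {self.modification_freq}"
            )
        n, _ = count_mismatches(self.guide_seq, self.ot_seq[:GUIDE_LEN])
        if n != self.mm_count:
            raise ValueError(
                f"mm_count {self.mm_count} inconsistent with sequences "
                f"({self.guide_name}: recomputed {n})"
            )


OFFTARGET_TABLE_COLUMNS = (
    "study", "assay", "guide_name", "guide_seq", "ot_seq", "mm_count",
    "modification_freq",
)


def read_offtarget_table(path) -> list[OffTargetRecord]:
    """Read a validated off-target TSV (header required, schema above)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(OFFTARGET_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"off-target table {path} lacks columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                OffTargetRecord(
                    study=row.study, assay=row.assay, guide_name=row.guide_name,
                    guide_seq=row.guide_seq, ot_seq=row.ot_seq,
                    mm_count=int(row.mm_count),
                    modification_freq=float(row.modification_freq),
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"off-target table row {i + 2}: {e}") from e
    return records


def write_offtarget_table(records: Iterable[OffTargetRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=OFFTARGET_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def tsai_frequency(reads_at_site: int, total_reads_for_guide: int) -> float:
    """Modification frequency proxy for read-count-only assays.

    Reads at one site divided by all reads for the guide; over a complete
    partition of a guide's reads the frequencies sum to 1.
    """
    if total_reads_for_guide <= 0:
        raise ValueError("total reads for guide must be positive")
    if not 0 <= reads_at_site <= total_reads_for_guide:
        raise ValueError("reads at site must be between 0 and the guide total")
    return reads_at_site / total_reads_for_guide


def clean_offtarget_dataset(
    records: Sequence[OffTargetRecord],
    gc_outlier_guides: Sequence[str] = DEFAULT_GC_OUTLIER_GUIDES,
    freq_floor: float = DEFAULT_FREQ_FLOOR,
) -> list[OffTargetRecord]:
    """Drop the named outlier guides, then keep records with
    modification_freq strictly above ``freq_floor``.

    Idempotent and order-independent. Outlier names absent from the data
    produce a warning, not an error.
    """
    present = {r.guide_name for r in records}
    for name in gc_outlier_guides:
        if name not in present:
            logger.warning("outlier guide %r not present in dataset", name)
    outliers = set(gc_outlier_guides)
    return [
        r for r in records
        if r.guide_name not in outliers and r.modification_freq > freq_floor
    ]


def mismatch_histogram(
    records: Sequence[OffTargetRecord], max_mm: int = 6
) -> dict[int, tuple[int, float]]:
    """Per-mismatch-count (record count, fraction of total) over 0..max_mm."""
    total = len(records)
    out = {}
    for k in range(max_mm + 1):
        n = sum(1 for r in records if r.mm_count == k)
        out[k] = (n, n / total if total else 0.0)
    return out


@dataclass
class LabeledCandidates:
    """Binary labels over a candidate universe plus the validated records
    the candidate search failed to produce (the failure mode of incomplete
    off-target searches)."""

    candidates: list[OffTargetHit]
    labels: np.ndarray  # bool, parallel to candidates
    missed: list[OffTargetRecord] = field(default_factory=list)


def label_candidates(
    candidates: Sequence[OffTargetHit], validated: Sequence[OffTargetRecord]
) -> LabeledCandidates:
    """Label each candidate positive iff its (guide, 20-mer site) appears
    in the validated set; validated records matching no candidate are
    returned in ``missed``, never silently dropped."""
    validated_keys = {(r.guide_name, r.ot_seq[:GUIDE_LEN]): r for r in validated}
    labels = np.zeros(len(candidates), dtype=bool)
    seen = set()
    for i, h in enumerate(candidates):
        key = (h.guide_name, h.site_seq)
        if key in validated_keys:
            labels[i] = True
            seen.add(key)
    missed = [r for k, r in validated_keys.items() if k not in seen]
    return LabeledCandidates(list(candidates), labels, missed)


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """ROC points and tie-corrected AUC (higher score = predicted positive).

    AUC is the Mann-Whitney U statistic over (positive, negative) pairs
    divided by n+ * n-, computed via average ranks so ties contribute 1/2.
    ROC points (fpr, tpr) are returned at every distinct threshold.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires at least one positive and one negative label")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(auc)


def tpr_fpr_at_cutoff(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> tuple[float, float]:
    """(TPR, FPR) when calling a candidate positive iff score >= cutoff."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("needs at least one positive and one negative label")
    pred = s >= cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    return tp / int(y.sum()), fp / int((~y).sum())


@dataclass(frozen=True)
class SpearmanCell:
    rho: Optional[float]
    p: Optional[float]
    n: int
    training_set: bool = False


def spearman_matrix(
    datasets: Mapping[str, pd.DataFrame],
    model_columns: Sequence[str],
    training_map: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict[tuple[str, str], SpearmanCell]:
    """Spearman rho (average ranks for ties) of each model column against
    measured ``activity``, per dataset.

    Each dataset DataFrame needs an ``activity`` column plus the model
    score columns; rows with a missing score are excluded pairwise. Cells
    with fewer than 3 pairs are reported missing (rho is None).
    ``training_map`` maps dataset name -> model names trained on it; such
    cells are flagged so they can be displayed as overfit artifacts.
    """
    training_map = training_map or {}
    out: dict[tuple[str, str], SpearmanCell] = {}
    for ds_name, df in datasets.items():
        if "activity" not in df.columns:
            raise ValueError(f"dataset {ds_name!r} lacks an 'activity' column")
        for model in model_columns:
            flagged = model in training_map.get(ds_name, ())
            if model not in df.columns:
                out[(ds_name, model)] = SpearmanCell(None, None, 0, flagged)
                continue
            pair = df[["activity", model]].dropna()
            if len(pair) < 3:
                out[(ds_name, model)] = SpearmanCell(None, None, len(pair), flagged)
                continue
            res = stats.spearmanr(pair[model], pair["activity"])
            out[(ds_name, model)] = SpearmanCell(
                float(res.statistic), float(res.pvalue), len(pair), flagged
            )
    return out


def spearman_matrix_to_tsv(cells: Mapping[tuple[str, str], SpearmanCell]) -> str:
    lines = ["dataset\tmodel\trho\tp\tn\ttraining_set"]
    for (ds, model), c in cells.items():
        rho = "" if c.rho is None else f"{c.rho:.4f}"
        p = "" if c.p is None else f"{c.p:.3g}"
        lines.append(f"{ds}\t{model}\t{rho}\t{p}\t{c.n}\t{int(c.training_set)}")
    return "\n".join(lines) + "\n"


def top_quartile_pr(
    predicted: Sequence[float], measured: Sequence[float]
) -> tuple[float, float]:
    """Precision/recall of the predicted top quartile against the measured
    top quartile.

    Both quartiles have size ceil(n/4); ties are broken by stable input
    order. precision = |P & M| / |P|, recall = |P & M| / |M| (the two
    sizes are equal, so precision = recall here; both are returned for
    symmetry with the general definition).
    """
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    n = len(pred)
    if n < 4 or len(meas) != n:
        raise ValueError("need at least 4 paired observations")
    k = math.ceil(n / 4)
    top_pred = set(np.argsort(-pred, kind="stable")[:k].tolist())
    top_meas = set(np.argsort(-meas, kind="stable")[:k].tolist())
    overlap = len(top_pred & top_meas)
    return overlap / k, overlap / k


@dataclass(frozen=True)
class LocusGuide:
    guide_id: str
    activity: float
    scores: Mapping[str, float]


@dataclass
class LocusDataset:
    """Guides grouped by target locus, each with measured activity and
    per-model prediction scores."""

    loci: dict[str, list[LocusGuide]]

    def __post_init__(self) -> None:
        for locus, guides in self.loci.items():
            if not guides:
                raise ValueError(f"locus {locus!r} has no guides")


def group_loci_by_distance(
    positions: Sequence[tuple[str, int]], max_dist: int = 3000
) -> list[int]:
    """Assign guides to loci: same locus iff on the same chromosome and
    closer than ``max_dist`` bp to the previous guide (after sorting).

    Returns a locus index per input guide, in input order.
    """
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    locus_of = [0] * len(positions)
    locus = -1
    prev = None
    for i in order:
        chrom, pos = positions[i]
        if prev is None or chrom != prev[0] or pos - prev[1] >= max_dist:
            locus += 1
        locus_of[i] = locus
        prev = (chrom, pos)
    return locus_of


def _stable_top_k(values: Sequence[float], k: int) -> set[int]:
    arr = np.asarray(values, dtype=float)
    return set(np.argsort(-arr, kind="stable")[:k].tolist())


def best_of_locus_test(
    loci: LocusDataset, model: str, draws: int = 100_000, seed: int = 0
) -> tuple[int, float]:
    """Does the model's top-scored guide hit the locus's best activity?

    observed = number of loci where the guide with the highest model score
    attains the locus's maximal activity value. Null: draw one guide
    uniformly per locus, count loci where the draw attains the maximal
    activity, repeat ``draws`` times; p = fraction of null draws with at
    least ``observed`` successes.
    """
    rng = np.random.default_rng(seed)
    observed = 0
    null_probs = []
    for locus, guides in loci.loci.items():
        acts = [g.activity for g in guides]
        best_act = max(acts)
        winners = [i for i, a in enumerate(acts) if a == best_act]
        top_scored = max(
            range(len(guides)), key=lambda i: (guides[i].scores[model], -i)
        )
        if top_scored in winners:
            observed += 1
        null_probs.append(len(winners) / len(guides))
    # one uniform draw per locus per repetition
    successes = np.zeros(draws, dtype=np.int64)
    for q in null_probs:
        successes += rng.random(draws) < q
    p = float((successes >= observed).mean())
    return observed, p


def top_two_test(
    loci: LocusDataset, model: str, draws: int = 100_000, seed: int = 0
) -> tuple[int, float]:
    """Do the model's top-2 guides contain one of the locus's top-2 measured?

    A locus succeeds when at least one of the two highest-scored guides
    has a measured activity among the locus's top two activity *values*
    (tie-inclusive, so the measured winner set can exceed two guides).
    Null: select two guides uniformly without replacement per locus; the
    per-locus success probability 1 - C(n-t, 2)/C(n, 2) (t = winner-set
    size) is sampled ``draws`` times. Loci with fewer than 2 guides are
    skipped with a warning. p = fraction of null draws with at least
    ``observed`` successes.
    """
    rng = np.random.default_rng(seed)
    observed = 0
    null_success = []
    for locus, guides in loci.loci.items():
        n = len(guides)
        if n < 2:
            logger.warning("locus %r has <2 guides; skipped", locus)
            continue
        acts = [g.activity for g in guides]
        top_vals = sorted(set(acts), reverse=True)[:2]
        winners = {i for i, a in enumerate(acts) if a >= top_vals[-1]}
        top_pred = _stable_top_k([g.scores[model] for g in guides], 2)
        if winners & top_pred:
            observed += 1
        t = len(winners)
        q_fail = ((n - t) * (n - t - 1)) / (n * (n - 1)) if n - t >= 2 else 0.0
        null_success.append(1.0 - q_fail)
    successes = np.zeros(draws, dtype=np.int64)
    for q in null_success:
        successes += rng.random(draws) < q
    p = float((successes >= observed).mean())
    return observed, p
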