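import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guidecraft import bench as bn
from guidecraft import fixtures as fx
from guidecraft.bench import (
    LocusDataset,
    LocusGuide,
    OffTargetRecord,
    best_of_locus_test,
    clean_offtarget_dataset,
    group_loci_by_distance,
    label_candidates,
    mismatch_histogram,
    roc_auc,
    spearman_matrix,
    top_quartile_pr,
    top_two_test,
    tpr_fpr_at_cutoff,
    tsai_frequency,
)
from guidecraft.otsearch import enumerate_offtargets
from guidecraft.otscore import score_hits


def record(guide="g1", freq=0.01, mm_positions=(5,), guide_seq="ACGTACGTACGTACGTACGT"):
    site = list(guide_seq)
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for p in mm_positions:
        site[p - 1] = alt[site[p - 1]]
    return OffTargetRecord(
        study="s", assay="a", guide_name=guide, guide_seq=guide_seq,
        ot_seq="".join(site) + "AGG", mm_count=len(mm_positions),
        modification_freq=freq,
    )


class TestTsaiFrequency:
    def test_half(self):
        assert tsai_frequency(50, 100) == 0.5

    def test_zero(self):
        assert tsai_frequency(0, 100) == 0.0

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(0)
        reads = rng.multinomial(1000, [1 / 7] * 7)
        total = int(reads.sum())
        assert sum(tsai_frequency(int(r), total) for r in reads) == pytest.approx(1.0)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            tsai_frequency(0, 0)


class TestCleaning:
    def test_record_at_floor_dropped(self):
        assert clean_offtarget_dataset([record(freq=0.001)]) == []

    def test_outlier_guide_dropped_regardless_of_freq(self):
        recs = [record(guide="VEGFA_site2", freq=0.5)]
        assert clean_offtarget_dataset(recs) == []

    def test_unknown_outlier_warns_not_errors(self, caplog):
        with caplog.at_level("WARNING"):
            out = clean_offtarget_dataset([record()], gc_outlier_guides=["nope"])
        assert len(out) == 1 and "not present" in caplog.text

    def test_hand_filter_on_mixed_fixture(self):
        recs = (
            [record(guide=f"k{i}", freq=0.01) for i in range(13)]
            + [record(guide=f"lo{i}", freq=0.0005) for i in range(3)]
            + [record(guide="VEGFA_site2", freq=0.3) for _ in range(2)]
            + [record(guide="HEK293_sgRNA4", freq=0.2) for _ in range(2)]
        )
        out = clean_offtarget_dataset(recs)
        assert len(out) == 13
        assert all(r.guide_name.startswith("k") for r in out)

    def test_idempotent_and_order_independent(self):
        recs = [record(guide=f"g{i}", freq=f) for i, f in enumerate((0.5, 0.0001, 0.002))]
        once = clean_offtarget_dataset(recs)
        assert clean_offtarget_dataset(once) == once
        rev = clean_offtarget_dataset(list(reversed(recs)))
        assert sorted(r.guide_name for r in rev) == sorted(r.guide_name for r in once)

    def test_alternative_floor_parameter(self):
        recs = [record(freq=0.0005)]
        assert clean_offtarget_dataset(recs, freq_floor=1e-4) == recs


class TestMismatchHistogram:
    def test_single_class(self):
        recs = [record(mm_positions=(1, 2, 3, 4)) for _ in range(5)]
        hist = mismatch_histogram(recs)
        assert hist[4] == (5, 1.0)
        assert sum(frac for _, frac in hist.values()) == pytest.approx(1.0)

    def test_hand_counts(self):
        recs = [record(mm_positions=(1, 2)) for _ in range(3)] + [
            record(mm_positions=(1, 2, 3)) for _ in range(6)
        ]
        hist = mismatch_histogram(recs)
        assert hist[2] == (3, pytest.approx(1 / 3))
        assert hist[3] == (6, pytest.approx(2 / 3))


class TestLabelCandidates:
    def test_empty_validated_all_negative(self, benchmark_study):
        genome, guides, _ = benchmark_study
        hits = enumerate_offtargets(guides[0], genome, max_mm=2)
        labeled = label_candidates(hits, [])
        assert not labeled.labels.any() and labeled.missed == []

    def test_planted_positives_counted_exactly(self, benchmark_study):
        genome, guides, records = benchmark_study
        candidates = []
        for g in guides:
            candidates.extend(enumerate_offtargets(g, genome, max_mm=4))
        labeled = label_candidates(candidates, records)
        positive_keys = {
            (h.guide_name, h.site_seq)
            for h, pos in zip(labeled.candidates, labeled.labels) if pos
        }
        assert positive_keys == {(r.guide_name, r.ot_seq[:20]) for r in records}
        assert labeled.missed == []

    def test_validated_absent_from_candidates_reported_missed(self):
        phantom = record(guide="ghost")
        labeled = label_candidates([], [phantom])
        assert labeled.missed == [phantom]


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0

    def test_all_ties_is_half(self):
        _, auc = roc_auc([0.5] * 10, [True] * 5 + [False] * 5)
        assert auc == 0.5

    def test_equals_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=200)
        scores[::5] = scores[1::5][:40]  # inject ties
        labels = rng.random(200) < 0.3
        _, auc = roc_auc(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_mannwhitney(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=150)
        labels = rng.random(150) < 0.4
        _, auc = roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert auc == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.random(100)
        labels = rng.random(100) < 0.5
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestTprFpr:
    def test_cutoff_below_min(self):
        assert tpr_fpr_at_cutoff([1, 2, 3, 4], [1, 0, 1, 0], 0.0) == (1.0, 1.0)

    def test_cutoff_above_max(self):
        assert tpr_fpr_at_cutoff([1, 2, 3, 4], [1, 0, 1, 0], 99.0) == (0.0, 0.0)

    def test_hand_confusion_matrix(self):
        scores = [0.1, 0.2, 0.45, 0.5, 0.55, 0.6, 0.7, 0.8, 0.9, 0.95]
        labels = [0, 0, 1, 0, 1, 0, 1, 1, 0, 1]
        # at cutoff 0.5: predicted positive = last 7; TP=4, FN=1, FP=3, TN=2
        tpr, fpr = tpr_fpr_at_cutoff(scores, labels, 0.5)
        assert tpr == pytest.approx(4 / 5)
        assert fpr == pytest.approx(3 / 5)

    def test_traces_onto_roc_curve(self):
        rng = np.random.default_rng(10)
        scores = rng.random(60)
        labels = rng.random(60) < 0.4
        points, _ = roc_auc(scores, labels)
        curve = {(round(f, 12), round(t, 12)) for f, t in points}
        for c in np.unique(scores):
            tpr, fpr = tpr_fpr_at_cutoff(scores, labels, c)
            assert (round(fpr, 12), round(tpr, 12)) in curve


class TestSpearmanMatrix:
    def test_identity_and_inverse(self):
        df = pd.DataFrame({"activity": [1.0, 2.0, 3.0, 4.0]})
        df["same"] = df["activity"]
        df["anti"] = -df["activity"]
        cells = spearman_matrix({"d": df}, ["same", "anti"])
        assert cells[("d", "same")].rho == pytest.approx(1.0)
        assert cells[("d", "anti")].rho == pytest.approx(-1.0)

    def test_small_n_reported_missing(self):
        df = pd.DataFrame({"activity": [1.0, 2.0], "m": [1.0, 2.0]})
        cells = spearman_matrix({"d": df}, ["m"])
        assert cells[("d", "m")].rho is None and cells[("d", "m")].n == 2

    def test_training_set_flagged(self):
        df = pd.DataFrame({"activity": [1.0, 2.0, 3.0, 4.0], "m": [1.0, 3.0, 2.0, 4.0]})
        cells = spearman_matrix({"d": df}, ["m"], {"d": ["m"]})
        assert cells[("d", "m")].training_set

    def test_recovers_latent_rho(self):
        df = fx.make_efficiency_dataset(n=50, latent_rho=0.7, seed=12)
        cells = spearman_matrix({"sim": df.rename(columns={"score": "m"})}, ["m"])
        assert cells[("sim", "m")].rho == pytest.approx(0.7, abs=0.15)


class TestTopQuartile:
    def test_identical_ranks_perfect(self):
        x = list(range(40))
        assert top_quartile_pr(x, x) == (1.0, 1.0)

    def test_anticorrelated_no_overlap(self):
        x = list(range(8))
        prec, rec = top_quartile_pr(x, x[::-1])
        assert prec == 0.0 and rec == 0.0

    def test_set_intersection_oracle(self):
        rng = np.random.default_rng(13)
        pred = rng.random(40)
        meas = rng.random(40)
        prec, rec = top_quartile_pr(pred, meas)
        k = math.ceil(40 / 4)
        top_p = set(np.argsort(-pred, kind="stable")[:k])
        top_m = set(np.argsort(-meas, kind="stable")[:k])
        assert prec == len(top_p & top_m) / k == rec

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            top_quartile_pr([1, 2, 3], [1, 2, 3])


def perfect_loci(n_loci, guides_per_locus):
    """Loci where the model score equals the measured activity."""
    return LocusDataset({
        f"L{i}": [
            LocusGuide(f"L{i}g{j}", float(j), {"m": float(j)})
            for j in range(guides_per_locus)
        ]
        for i in range(n_loci)
    })


class TestBestOfLocus:
    def test_single_locus_single_guide(self):
        lds = LocusDataset({"L": [LocusGuide("g", 1.0, {"m": 0.5})]})
        assert best_of_locus_test(lds, "m", draws=1000, seed=1) == (1, 1.0)

    def test_perfect_model_p_matches_binomial(self):
        # 8 loci x 3 guides, model always right: null p = (1/3)^8
        lds = perfect_loci(8, 3)
        draws = 100_000
        obs, p = best_of_locus_test(lds, "m", draws=draws, seed=2)
        assert obs == 8
        exact = (1 / 3) ** 8
        se = math.sqrt(exact * (1 - exact) / draws)
        assert abs(p - exact) <= 3 * se + 1e-12

    def test_fixed_seed_reproducible(self):
        lds = perfect_loci(5, 3)
        a = best_of_locus_test(lds, "m", draws=20_000, seed=42)
        assert a == best_of_locus_test(lds, "m", draws=20_000, seed=42)

    def test_across_seed_spread_within_mc_error(self):
        lds = perfect_loci(4, 2)
        draws = 50_000
        exact = 0.5 ** 4
        ps = [best_of_locus_test(lds, "m", draws=draws, seed=s)[1] for s in range(10)]
        se = math.sqrt(exact * (1 - exact) / draws)
        assert all(abs(p - exact) <= 4 * se for p in ps)

    def test_empty_locus_errors(self):
        with pytest.raises(ValueError):
            LocusDataset({"L": []})


class TestTopTwo:
    def test_two_guide_loci_always_succeed(self):
        lds = perfect_loci(6, 2)
        obs, p = top_two_test(lds, "m", draws=1000, seed=3)
        assert obs == 6 and p == 1.0

    def test_perfect_model_matches_hypergeometric(self):
        # 11 loci of 20 guides, model = measured: observed 11; null per-locus
        # success 1 - C(18,2)/C(20,2); p = q^11
        lds = perfect_loci(11, 20)
        draws = 100_000
        obs, p = top_two_test(lds, "m", draws=draws, seed=4)
        assert obs == 11
        q = 1 - (18 * 17) / (20 * 19)
        exact = q ** 11
        se = math.sqrt(exact * (1 - exact) / draws)
        assert abs(p - exact) <= 3 * se + 1e-12

    def test_small_locus_skipped_with_warning(self, caplog):
        lds = LocusDataset({
            "ok": [LocusGuide("a", 1.0, {"m": 1.0}), LocusGuide("b", 0.0, {"m": 0.0})],
            "tiny": [LocusGuide("c", 1.0, {"m": 1.0})],
        })
        with caplog.at_level("WARNING"):
            obs, _ = top_two_test(lds, "m", draws=1000, seed=5)
        assert obs == 1 and "skipped" in caplog.text


def test_group_loci_by_distance():
    positions = [("chr1", 0), ("chr1", 1000), ("chr1", 10_000), ("chr2", 10_500)]
    assert group_loci_by_distance(positions) == [0, 0, 1, 2]


def test_offtarget_table_round_trip(tmp_path, benchmark_study):
    _, _, records = benchmark_study
    p = tmp_path / "ot.tsv"
    bn.write_offtarget_table(records, p)
    back = bn.read_offtarget_table(p)
    assert back == records


def test_offtarget_table_schema_violation_named(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("study\tassay\n s\ta\n")
    with pytest.raises(ValueError, match="lacks columns"):
        bn.read_offtarget_table(p)
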