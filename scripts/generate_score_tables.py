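"""Regenerate the packaged score-constant TSVs under src/guidecraft/data/.

Two kinds of files are written:

* transcribed constants (mit_weights.tsv, cfd_pam.tsv): numeric values of
  the widely reproduced canonical tables;
* synthetic stand-ins (*_synthetic.tsv): deterministic tables that follow
  the published qualitative structure of the corresponding source (zone
  layout, positional trends, wobble tolerance, link function and window)
  but whose numeric values are generated here, not transcribed. Every such
  file says so in its header comment.

Run from the repository root:  python scripts/generate_score_tables.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parent.parent / "src" / "guidecraft" / "data"

# Canonical MIT per-position mismatch weights, 1 = PAM-distal (5').
MIT_WEIGHTS = [
    0.0, 0.0, 0.014, 0.0, 0.0,
    0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732,
    0.828, 0.615, 0.804, 0.685, 0.583,
]

# Canonical CFD PAM penalties, keyed by the last two PAM bases (N--).
CFD_PAM2 = {
    "AA": 0.0, "AC": 0.0, "AG": 0.259259259, "AT": 0.0,
    "CA": 0.0, "CC": 0.0, "CG": 0.107142857, "CT": 0.0,
    "GA": 0.069444444, "GC": 0.022222222, "GG": 1.0, "GT": 0.016129032,
    "TA": 0.0, "TC": 0.0, "TG": 0.038961039, "TT": 0.0,
}

RNA = "ACGU"
DNA = "ACGT"

# Per-mismatch-pair tolerance factors for the synthetic CFD mismatch table,
# keyed (guide RNA base, genome protospacer-strand base); matches are
# (A,A),(C,C),(G,G),(U,T). Wobble pairings with the target strand — guide G
# opposite target U (genome A) and guide U opposite target G (genome C) —
# are the most tolerated, the qualitative ordering reported for Cas9
# mismatch tolerance. Values are synthetic.
PAIR_TOLERANCE = {
    ("G", "A"): 0.65, ("U", "C"): 0.60,
    ("A", "G"): 0.45, ("C", "T"): 0.42,
    ("G", "C"): 0.38, ("U", "A"): 0.35,
    ("A", "C"): 0.30, ("C", "A"): 0.28,
    ("U", "G"): 0.26, ("G", "T"): 0.24,
    ("A", "T"): 0.22, ("C", "G"): 0.15,
}


def rna(b: str) -> str:
    return "U" if b == "T" else b


def write(name: str, header: str, rows: list[str]) -> None:
    path = DATA / name
    path.write_text(header + "\n".join(rows) + "\n")
    print(f"wrote {path} ({len(rows)} rows)")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    write(
        "mit_weights.tsv",
        "# MIT off-target per-position mismatch weights; pos 1 = PAM-distal.\n"
        "pos\tweight\n",
        [f"{p}\t{w}" for p, w in enumerate(MIT_WEIGHTS, start=1)],
    )

    rows = []
    for n in DNA:
        for two, pen in sorted(CFD_PAM2.items()):
            rows.append(f"{n}{two}\t{pen:.9f}")
    write(
        "cfd_pam.tsv",
        "# CFD PAM penalties; canonical values keyed by the last two PAM bases,\n"
        "# expanded over the (ignored) first base.\n"
        "pam\tpenalty\n",
        rows,
    )

    # Synthetic CFD mismatch table: penalty = pair tolerance x positional
    # factor declining linearly toward the PAM; matches are 1.0.
    rows = []
    for p in range(1, 21):
        pos_tol = 1.0 - 0.8 * (p - 1) / 19.0
        for r in RNA:
            for d in DNA:
                if rna(d) == r:
                    pen = 1.0
                else:
                    pen = round(PAIR_TOLERANCE[(r, d)] * pos_tol, 6)
                rows.append(f"{p}\t{r}\t{d}\t{pen}")
    write(
        "cfd_mm_synthetic.tsv",
        "# SYNTHETIC stand-in for the CFD mismatch penalty table: pairwise\n"
        "# tolerances x linear positional decline toward the PAM; not the\n"
        "# published empirical values.\n"
        "pos\tguide_base\tgenome_base\tpenalty\n",
        rows,
    )

    # Synthetic CROP-IT zone weights: three PAM-anchored zones (5 | 7 | 8 nt,
    # distal to proximal) with weight rising toward the PAM.
    zone_weight = [15] * 5 + [30] * 7 + [50] * 8
    write(
        "cropit_synthetic.tsv",
        "# SYNTHETIC stand-in for CROP-IT per-position cleavage weights:\n"
        "# piecewise-constant over three PAM-anchored zones; values synthetic.\n"
        "pos\tweight\n",
        [f"{p}\t{w}" for p, w in enumerate(zone_weight, start=1)],
    )

    # Synthetic per-position aggregate cleavage frequencies: tolerance of a
    # mismatch declines toward the PAM; max-normalized to 1.
    write(
        "hsu_synthetic.tsv",
        "# SYNTHETIC stand-in for the normalized aggregate per-position\n"
        "# mismatch cleavage frequencies (max over positions = 1).\n"
        "pos\tfreq\n",
        [f"{p}\t{round(1.0 - 0.95 * (p - 1) / 19.0, 6)}" for p in range(1, 21)],
    )

    # Synthetic Doench-2014-style logistic model: 30-mer context
    # (4 upstream + 20 protospacer + 3 PAM + 3 downstream).
    rng = np.random.default_rng(20140101)
    feats: dict[str, float] = {}
    while len(feats) < 40:
        p = int(rng.integers(1, 31))
        b = "ACGT"[rng.integers(0, 4)]
        feats.setdefault(f"{b}@{p}", round(float(rng.normal(0.0, 0.15)), 4))
    while len(feats) < 70:
        p = int(rng.integers(1, 30))
        bb = "ACGT"[rng.integers(0, 4)] + "ACGT"[rng.integers(0, 4)]
        feats.setdefault(f"{bb}@{p}", round(float(rng.normal(0.0, 0.10)), 4))
    rows = ["intercept\t0.5976", "gc_low\t-0.2026", "gc_high\t-0.1666"]
    rows += [f"{k}\t{v}" for k, v in sorted(feats.items())]
    write(
        "doench2014_synthetic.tsv",
        "# SYNTHETIC stand-in for the Doench-2014-style logistic position\n"
        "# weight model; feature layout and link real, weights synthetic.\n"
        "# name=doench2014\twindow=4,3\tlink=logistic\n"
        "feature\tweight\n",
        rows,
    )

    # Synthetic Moreno-Mateos-style identity-link model: 35-mer context
    # (6 upstream + 20 protospacer + 3 PAM + 6 downstream).
    rng = np.random.default_rng(20150101)
    feats = {}
    while len(feats) < 45:
        p = int(rng.integers(1, 36))
        b = "ACGT"[rng.integers(0, 4)]
        feats.setdefault(f"{b}@{p}", round(float(rng.normal(0.0, 0.08)), 4))
    while len(feats) < 80:
        p = int(rng.integers(1, 35))
        bb = "ACGT"[rng.integers(0, 4)] + "ACGT"[rng.integers(0, 4)]
        feats.setdefault(f"{bb}@{p}", round(float(rng.normal(0.0, 0.06)), 4))
    rows = ["intercept\t0.1839"]
    rows += [f"{k}\t{v}" for k, v in sorted(feats.items())]
    write(
        "moreno_mateos_synthetic.tsv",
        "# SYNTHETIC stand-in for the Moreno-Mateos-style identity-link\n"
        "# position weight model; layout and link real, weights synthetic.\n"
        "# name=moreno_mateos\twindow=6,6\tlink=identity\n"
        "feature\tweight\n",
        rows,
    )


if __name__ == "__main__":
    main()
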