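"""Promoter TFBS frequency: regulated genes vs a 198-gene control cohort.

For each motif, counts the genes whose 2000-bp upstream window carries at
least one site (both strands) in the regulated list and in a seeded
random cohort of never-regulated genes, then applies the pooled
two-proportion z-test.  The planted Hnf4a-like imbalance (11.5% vs 1.5%)
should be flagged; the fixture motifs without planted imbalance should
generally not be.

Run after 03_differential_expression.py:  python analysis/05_tfbs.py
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from gillzinc import io, tfbs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    promoters = io.read_promoters(args.datadir / "promoters.fa", window=2000)
    motifs = io.read_motifs(args.datadir / "motifs.tsv")
    truth = io.read_truth(args.datadir / "sim_truth.tsv")
    regulated = io.read_gene_list(args.outdir / "regulated_genes.txt")

    fg_ids = sorted(regulated & set(promoters.sequences))
    ever_regulated = set(truth.index[truth["regulated"]])
    cohort = tfbs.select_control_cohort(
        promoters.sequences, ever_regulated, size=198, seed=args.seed
    )
    fg = tfbs.PromoterSet({g: promoters.sequences[g] for g in fg_ids})
    bg = tfbs.PromoterSet({g: promoters.sequences[g] for g in sorted(cohort)})
    print(f"{len(fg_ids)} regulated promoters vs {len(cohort)} control promoters")

    rows = []
    for motif in motifs:
        cmp_ = tfbs.compare_tfbs_frequency(
            tfbs.scan_promoters(fg, motif), tfbs.scan_promoters(bg, motif)
        )
        rows.append(asdict(cmp_))
        flag = "*" if cmp_.significant else " "
        print(f" {flag} {motif.name:<18} {100 * cmp_.p1:5.1f}% vs {100 * cmp_.p2:5.1f}%  "
              f"z={cmp_.z:+6.2f}  p={cmp_.p:.3g}")
    pd.DataFrame(rows).to_csv(args.outdir / "tfbs_comparison.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
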