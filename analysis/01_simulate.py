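"""Generate the synthetic study bundle: expression arrays plus every side input.

Emulates the source experiment's design — 16,000 reporters, zinc-depleted
vs control gills at 0.3/1/4/7/14 days in quintuplicate with one Day-4
control replicate missing — and writes the expression matrices, ground
truth, promoters with a planted Hnf4a-like motif imbalance, an annotation
table with one planted term, and a curated-style edge table.

Run from the repository root:  python analysis/01_simulate.py [--seed N]
"""

import argparse
from pathlib import Path

from gillzinc import io, tfbs
from gillzinc.simdata import (
    SimulationConfig,
    simulate_annotation_table,
    simulate_expression_dataset,
    simulate_interaction_table,
    simulate_promoter_set,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    outdir = args.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    dataset, truth = simulate_expression_dataset(cfg)
    io.write_expression_dataset(dataset, outdir)
    io.write_truth(truth, outdir / "sim_truth.tsv")
    n_reg = int(truth["regulated"].sum())
    print(f"expression: {dataset.M.shape[0]} reporters x {dataset.M.shape[1]} arrays, "
          f"{n_reg} regulated ({100 * n_reg / cfg.n_reporters:.1f}%), "
          f"{int(truth['persistent'].sum())} persistent")

    regulated = sorted(truth.index[truth["regulated"]])
    motif = tfbs.MotifPattern("Hnf4a_fixture", "GGNCAAAGKTCA")
    promoters, sites = simulate_promoter_set(
        regulated, 1500, [(motif, 0.115, 0.015)], seed=args.seed + 2
    )
    io.write_promoters(promoters, outdir / "promoters.fa")
    sites.to_csv(outdir / "planted_sites.tsv", sep="\t", index=False)
    io.write_motifs(io.read_motifs(io.demo_motifs_path()), outdir / "motifs.tsv")
    print(f"promoters: {len(promoters.sequences)} x {promoters.window} bp, "
          f"{len(sites)} planted {motif.name} sites")

    term_map, _ = simulate_annotation_table(
        cfg.n_reporters, 100, term_size_range=(10, 80),
        planted=[("planted_term", 50, regulated[:40], 25)], seed=args.seed + 1,
    )
    term_map = {
        t: {g if g.startswith("rep") else "rep" + g[1:] for g in genes}
        for t, genes in term_map.items()
    }
    io.write_gmt(term_map, outdir / "terms.gmt")
    print(f"annotation: {len(term_map)} terms incl. planted_term (overlap 25/40)")

    edges = simulate_interaction_table(
        regulated + ["Zn", "Mtf1"], extra_nodes=100, edge_density=0.01,
        seed=args.seed + 4,
    )
    io.write_edges(edges, outdir / "edges.tsv")
    print(f"interactions: {len(edges)} curated-style edges")


if __name__ == "__main__":
    main()
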