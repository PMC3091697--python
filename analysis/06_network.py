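"""Assemble the direct-interaction network and rank its hubs.

Induces the curated edge table on the regulated genes plus the declared
seed nodes (the zinc ion and Mtf1), reports components and isolated
members, and ranks nodes by unique-neighbour degree.

Run after 03_differential_expression.py:  python analysis/06_network.py
"""

import argparse
from pathlib import Path

import pandas as pd

from gillzinc import io
from gillzinc.network import build_direct_interaction_network, export_graphml, rank_hubs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    edges = io.read_edges(args.datadir / "edges.tsv")
    regulated = io.read_gene_list(args.outdir / "regulated_genes.txt")

    net = build_direct_interaction_network(regulated, ("Zn", "Mtf1"), edges)
    hubs = rank_hubs(net)
    hubs.to_csv(args.outdir / "network_hubs.tsv", sep="\t", index=False)
    pd.DataFrame(net.edges, columns=["source", "target", "type", "directed"]).to_csv(
        args.outdir / "network_edges.tsv", sep="\t", index=False
    )
    export_graphml(net, args.outdir / "network.graphml")

    comps = net.connected_components()
    print(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges, "
          f"{len(comps)} components ({len(net.isolated)} isolated members)")
    print("top hubs:")
    print(hubs.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
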