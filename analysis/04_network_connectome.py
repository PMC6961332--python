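#!/usr/bin/env python
"""Minimum subnetworks, closest-known-gene routes and the distance tree.

Extracts the Steiner-style minimum subnetwork over the selected case
genes at the high (0.9) and medium (0.4) confidence floors, reports each
candidate gene's closest known disease gene with its route (distance,
route string, degrees of separation, connectome percentile), and writes
a UPGMA tree of the biological distance matrix. Outputs under
results/network/.
"""

import pandas as pd
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
FILT = ROOT / "results" / "filtering"
OUT = ROOT / "results" / "network"

from chdpath.connectome import (  # noqa: E402
    PpiGraph, closest_known, distance_matrix, mean_distance_to_set,
    minimum_subnetwork, upgma_tree)
from chdpath.simulate import SyntheticTruth  # noqa: E402


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    graph = PpiGraph.from_tsv(SYN / "interactome.tsv")
    truth = SyntheticTruth.from_json(SYN / "truth.json")
    known = set(truth.known_genes)
    burden = pd.read_csv(FILT / "case_burden.tsv", sep="\t")
    case_genes = sorted(burden.loc[burden["selected"], "gene"])
    candidates = [g for g in case_genes if g not in known]

    for floor in (0.9, 0.4):
        sub = minimum_subnetwork(case_genes, graph, floor, known)
        sub.to_sif(OUT / f"subnetwork_conf{int(floor * 100)}.sif")
        print(f"floor {floor}: subnetwork of {len(sub.nodes)} genes, "
              f"{len(sub.focus_genes)} input genes, "
              f"{sub.known_count} known disease genes "
              f"({len(sub.dropped_seeds)} seeds unreachable)")

    rows = []
    for cand in candidates:
        res = closest_known(cand, known, graph)
        rows.append({
            "candidate": cand, "known": res.gene_b,
            "distance": round(res.distance, 2),
            "p_value": res.percentile_p,
            "route": res.route_str,
            "degrees_of_separation": res.degrees_of_separation,
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "closest_known.tsv", sep="\t", index=False)
    in_top1 = (table["p_value"] <= 0.01).sum()
    print(f"{in_top1}/{len(table)} candidates sit in the top 1% of their "
          f"closest known gene's connectome")

    means = mean_distance_to_set(candidates, known, graph)
    means.to_csv(OUT / "mean_distance_to_known.tsv", sep="\t", index=False)
    print(f"mean candidate-to-known biological distance: "
          f"{means['mean_distance'].mean():.2f} "
          f"(sd {means['mean_distance'].std():.2f})")

    tree_genes = sorted(set(case_genes) | known)
    dm = distance_matrix(tree_genes, graph)
    (OUT / "distance_tree.nwk").write_text(
        upgma_tree(tree_genes, dm.values) + "\n")
    print(f"UPGMA tree over {len(tree_genes)} genes -> distance_tree.nwk")


if __name__ == "__main__":
    main()
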