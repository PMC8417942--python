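#!/usr/bin/env python
"""Pairwise co-enrichment and network stratification.

Fisher-overlap p-values for every variable pair, binarized at the strict
0.5th percentile of all pairwise significances, plus the per-node
most-enriched-variable stratification ("which variable colours each
node").
"""

import pickle
from pathlib import Path

from microstrat.coenrichment import (
    coenrichment_matrix,
    stratify_nodes,
    threshold_binarize,
)
from microstrat.mapper import read_network

OUT = Path("results/analysis")


def main() -> None:
    net = read_network(OUT / "network.graphml", OUT / "network_members.json")
    with open(OUT / "safe_results.pkl", "rb") as fh:
        results = pickle.load(fh)

    p_matrix = coenrichment_matrix(results, len(net.nodes))
    coe = threshold_binarize(p_matrix, percentile=0.5)
    coe.p_matrix.to_csv(OUT / "coenrichment_p.tsv", sep="\t")
    coe.binary_matrix.to_csv(OUT / "coenrichment_binary.tsv", sep="\t")
    print(f"binarization threshold (0.5th pct of pairwise p): {coe.threshold:.3g}")

    pairs = []
    names = coe.variables
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            if coe.binary_matrix.iloc[i, j] == 1:
                pairs.append((a, names[j], coe.p_matrix.iloc[i, j]))
    pairs.sort(key=lambda t: t[2])
    print(f"{len(pairs)} significantly co-enriched pairs; strongest:")
    for a, b, p in pairs[:10]:
        print(f"  {a} ~ {b}  (p={p:.3g})")

    strat = stratify_nodes(results)
    strat.to_csv(OUT / "stratification.tsv", sep="\t")
    counts = strat["winner"].value_counts()
    print("node stratification winners (top 8):")
    print(counts.head(8).to_string())


if __name__ == "__main__":
    main()
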