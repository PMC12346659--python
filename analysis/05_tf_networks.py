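#!/usr/bin/env python
"""Per-cluster transcription-factor networks: regulon-based TF activity,
correlation-threshold (|r| >= 0.4) networks over TF activity profiles
within each tumor cluster, centrality computation, hub/bottleneck
flags with regulatory sign, and a hypergeometric over-representation
check of the top hub's regulon among gradient-associated genes.
"""

from pathlib import Path

import pandas as pd

from crcmeth.io_formats import read_matrix, read_regulons, write_graph
from crcmeth.network import (
    build_network,
    centrality,
    hub_regulatory_sign,
    identify_hubs,
    infer_tf_activity,
)
from crcmeth.scores import ora_hypergeometric

DATA = Path("scratch/data")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expression = read_matrix(DATA / "expression.tsv")
    regulons = read_regulons(DATA / "regulons.tsv")
    labels = pd.read_csv(OUT / "cluster_labels.tsv", sep="\t", index_col=0)["cluster"]

    z = expression.sub(expression.mean(axis=1), axis=0).div(
        expression.std(axis=1, ddof=1), axis=0
    )
    activity, excluded, n_targets = infer_tf_activity(z, regulons)
    print(f"TF activity inferred for {activity.shape[0]} TFs "
          f"({len(excluded)} excluded for <3 targets)")

    net_dir = OUT / "networks"
    net_dir.mkdir(exist_ok=True)
    all_cent = []
    for cluster in (2, 3, 4):
        members = labels[labels == cluster].index
        graph = build_network(activity[members], threshold=0.4)
        cent = identify_hubs(centrality(graph))
        cent["cluster"] = f"CL{cluster}"
        cent["regulatory_sign"] = [
            hub_regulatory_sign(tf, activity.loc[tf, members], z[members], regulons)
            if cent.loc[tf, "hub"] else None
            for tf in cent.index
        ]
        all_cent.append(cent)
        write_graph(graph, net_dir / f"CL{cluster}.sif", "sif")
        write_graph(graph, net_dir / f"CL{cluster}.graphml", "graphml")
        hubs = cent[cent["hub"]].index.tolist()
        print(f"CL{cluster}: {graph.number_of_edges()} edges, hubs: {hubs}")

    table = pd.concat(all_cent).rename_axis("tf").reset_index()
    table.to_csv(OUT / "tf_centralities.tsv", sep="\t", index=False)

    # over-representation of the strongest hub's regulon among the genes
    # most correlated with the methylation gradient
    top = table.sort_values("degree", ascending=False).iloc[0]["tf"]
    gradient = labels.astype(float)
    corr = z[labels.index].T.corrwith(gradient)
    query = corr.abs().nlargest(60).index.tolist()
    universe = z.index.tolist()
    sets = {
        tf: sub["target"].tolist() for tf, sub in regulons.groupby("tf")
    }
    ora = ora_hypergeometric(query, universe, sets)
    ora.to_csv(OUT / "hub_regulon_ora.tsv", sep="\t", index=False)
    print(f"\ntop hub: {top}; regulon over-representation among "
          f"gradient-correlated genes (top 3 sets):")
    print(ora.head(3).round(4).to_string(index=False))


if __name__ == "__main__":
    main()
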