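#!/usr/bin/env python
"""Clinical contrasts across the methylation clusters: EMT expression
scores (Kruskal-Wallis + pairwise BH Wilcoxon), mutation burden, and
Kaplan-Meier survival with pairwise log-rank tests among the tumor
clusters (CL1 normals excluded, follow-up truncated at 1000 days).
"""

from pathlib import Path

import pandas as pd

from crcmeth.io_formats import read_clinical, read_matrix
from crcmeth.scores import compare_groups, emt_score, mutation_burden
from crcmeth.survival import km_estimate, pairwise_logrank, truncate_followup

DATA = Path("scratch/data")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expression = read_matrix(DATA / "expression.tsv")
    labels = pd.read_csv(OUT / "cluster_labels.tsv", sep="\t", index_col=0)["cluster"]
    cluster_name = labels.map(lambda c: f"CL{c}")

    scores, skipped = emt_score(expression)
    scores = scores.loc[labels.index]
    scores.rename("emt_score").to_csv(OUT / "emt_scores.tsv", sep="\t")
    emt = compare_groups(scores.to_numpy(), cluster_name.loc[scores.index].to_numpy())
    emt["pairwise"].to_csv(OUT / "emt_pairwise.tsv", sep="\t", index=False)
    by_cluster = scores.groupby(cluster_name).mean()
    print(f"EMT score by cluster (KW p={emt['kw_p']:.2e}; "
          f"{len(skipped)} panel genes skipped):")
    print(by_cluster.round(2).to_string())
    print(f"highest EMT score in {by_cluster.idxmax()}")

    clinical = read_clinical(DATA / "clinical.tsv")
    burden = mutation_burden(clinical, labels=cluster_name.to_dict())
    burden["comparison"]["pairwise"].to_csv(
        OUT / "mutation_burden_pairwise.tsv", sep="\t", index=False
    )
    mean_burden = burden["totals"].groupby(cluster_name).mean()
    print(f"\nmutation burden by cluster "
          f"(KW p={burden['comparison']['kw_p']:.2e}):")
    print(mean_burden.round(2).to_string())

    tumor_labels = {s: f"CL{c}" for s, c in labels.items() if c != 1}
    truncated = truncate_followup(clinical, limit=1000)
    pairs = [("CL2", "CL3"), ("CL2", "CL4"), ("CL3", "CL4")]
    table = pairwise_logrank(truncated, tumor_labels, pairs=pairs)
    table.to_csv(OUT / "survival_pairwise_logrank.tsv", sep="\t", index=False)
    print("\npairwise log-rank over tumor clusters (1000-day truncation):")
    print(table[["group_a", "group_b", "statistic", "p"]].round(4).to_string(index=False))

    rows = []
    for cl in ("CL2", "CL3", "CL4"):
        recs = [r for r in truncated if tumor_labels.get(r.sample_id) == cl]
        curve = km_estimate([r.time for r in recs], [r.event for r in recs])
        rows.append({"cluster": cl, "S(500)": curve.survival_at(500),
                     "S(1000)": curve.survival_at(1000)})
    km = pd.DataFrame(rows)
    km.to_csv(OUT / "km_summary.tsv", sep="\t", index=False)
    print("\nKaplan-Meier survival probabilities:")
    print(km.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
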