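"""Regulon-based TF activity, correlation-threshold networks, and
hub/bottleneck identification.

TF activity is a mode-signed mean of target z-scores (a deliberately
simple surrogate for rank-enrichment activity inference; the downstream
summaries operate on the network, not the inference engine).  Networks
connect node profiles whose Pearson correlation magnitude reaches the
threshold (0.4 by default); hubs and bottlenecks are nodes in the top
decile of degree and betweenness respectively (ties inclusive).
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "infer_tf_activity",
    "build_network",
    "centrality",
    "identify_hubs",
    "hub_regulatory_sign",
]

MIN_TARGETS = 3  # TFs with fewer present regulon targets are not scored


def infer_tf_activity(expression_z: pd.DataFrame, regulons: pd.DataFrame):
    """activity(tf, sample) = mean over targets of mode * z_target.

    ``expression_z``: genes x samples, z-scored per gene across the
    cohort; ``regulons``: frame with tf/target/mode (+-1) columns.
    TFs with fewer than MIN_TARGETS targets present in the matrix are
    excluded and reported.  Returns (activity DataFrame tf x sample,
    excluded list, n_targets_used Series).
    """
    rows, n_used, excluded = {}, {}, []
    for tf, sub in regulons.groupby("tf"):
        present = sub[sub["target"].isin(expression_z.index)]
        if len(present) < MIN_TARGETS:
            excluded.append(tf)
            continue
        z = expression_z.loc[present["target"]].to_numpy(dtype=float)
        modes = present["mode"].to_numpy(dtype=float)[:, None]
        rows[tf] = pd.Series(
            (modes * z).mean(axis=0), index=expression_z.columns
        )
        n_used[tf] = len(present)
    activity = pd.DataFrame(rows).T if rows else pd.DataFrame(
        columns=expression_z.columns
    )
    return activity, excluded, pd.Series(n_used, dtype=int)


def build_network(profile_matrix: pd.DataFrame, threshold: float = 0.4) -> nx.Graph:
    """Graph over profile rows: edge iff |Pearson r| >= threshold.

    Edge attributes: ``weight`` (r) and ``sign`` (+-1).  Zero-variance
    profiles produce no edges.  No self-edges.
    """
    nodes = list(profile_matrix.index)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    if len(nodes) < 2 or profile_matrix.shape[1] < 2:
        return graph
    values = profile_matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                graph.add_edge(
                    nodes[i], nodes[j], weight=float(r),
                    sign=1 if r >= 0 else -1,
                )
    return graph


def centrality(graph: nx.Graph) -> pd.DataFrame:
    """Degree, normalized betweenness, and harmonic closeness per node.

    Computed on the unweighted undirected skeleton; harmonic closeness
    (sum of inverse distances / (n-1)) handles disconnected graphs.
    """
    nodes = list(graph.nodes)
    if not nodes:
        return pd.DataFrame(columns=["degree", "betweenness", "closeness"])
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    harmonic = nx.harmonic_centrality(graph)
    n = len(nodes)
    scale = 1.0 / (n - 1) if n > 1 else 0.0
    return pd.DataFrame({
        "degree": pd.Series(degree),
        "betweenness": pd.Series(betweenness),
        "closeness": pd.Series(harmonic) * scale,
    }).loc[nodes]


def identify_hubs(centralities: pd.DataFrame, degree_quantile: float = 0.9,
                  betweenness_quantile: float = 0.9) -> pd.DataFrame:
    """Flag hubs (top-quantile degree) and bottlenecks (top-quantile
    betweenness); ties at the quantile value take the flag."""
    if centralities.empty:
        return centralities.assign(hub=pd.Series(dtype=bool),
                                   bottleneck=pd.Series(dtype=bool))
    deg_cut = centralities["degree"].quantile(degree_quantile)
    bet_cut = centralities["betweenness"].quantile(betweenness_quantile)
    out = centralities.copy()
    out["hub"] = centralities["degree"] >= deg_cut
    out["bottleneck"] = centralities["betweenness"] >= bet_cut
    return out


def hub_regulatory_sign(tf: str, activity: pd.Series,
                        expression_z: pd.DataFrame,
                        regulons: pd.DataFrame) -> Optional[int]:
    """Sign of the mean activity-to-target correlation for a hub TF.

    Positive: the hub drives its downstream targets up as its activity
    rises; negative: represses.  None when undefined (constant profiles
    or <1 present target).
    """
    targets = regulons.loc[regulons["tf"] == tf, "target"]
    targets = [t for t in targets if t in expression_z.index]
    if not targets or activity.std() == 0:
        return None
    corrs = []
    a = activity.to_numpy(dtype=float)
    for t in targets:
        z = expression_z.loc[t, activity.index].to_numpy(dtype=float)
        if np.std(z) == 0:
            continue
        corrs.append(np.corrcoef(a, z)[0, 1])
    if not corrs:
        return None
    mean = float(np.mean(corrs))
    return 1 if mean >= 0 else -1
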