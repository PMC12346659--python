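"""Resampling consensus clustering, Ward assignment, and PCA embedding.

Consensus clustering follows the standard resampling scheme: for each of
``reps`` iterations a fraction ``p_item`` of samples (and ``p_feature``
of features) is drawn without replacement, hierarchically clustered
(average linkage, Euclidean distance) and cut at every k; the consensus
matrix entry for a sample pair is the number of co-assignments divided
by the number of co-samplings.  Per-k labels come from average-linkage
clustering of (1 - consensus); k selection is reported through the
delta-area of the consensus CDF.  The headline assignment for the
downstream analyses is Ward/Euclidean on the z-matrix with clusters
renumbered by increasing mean methylation (CL1 = lowest, i.e. normal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = ["ConsensusResult", "consensus_cluster", "assign_clusters", "pca_embed"]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels, CDFs and delta-areas."""

    consensus: dict  # k -> DataFrame (samples x samples) in [0, 1]
    labels: dict  # k -> Series sample -> 1..k
    cdf_grid: np.ndarray
    cdfs: dict  # k -> CDF values over cdf_grid
    areas: dict  # k -> area under the CDF
    delta_area: dict  # k -> relative increase in area

    @property
    def best_k(self) -> int:
        return max(self.delta_area, key=self.delta_area.get)


def consensus_cluster(z_matrix: pd.DataFrame, k_min: int = 3, k_max: int = 20,
                      reps: int = 1000, p_item: float = 0.8,
                      p_feature: float = 1.0, seed: int = 0) -> ConsensusResult:
    """Resampling consensus clustering of a features x samples matrix."""
    samples = list(z_matrix.columns)
    n = len(samples)
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be < number of samples ({n})")
    values = z_matrix.to_numpy(dtype=float)
    m = values.shape[0]
    rng = np.random.default_rng(seed)
    n_items = math.ceil(p_item * n)
    n_feats = math.ceil(p_feature * m)

    ks = list(range(k_min, k_max + 1))
    co_assign = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))

    for _ in range(reps):
        cols = np.sort(rng.choice(n, size=n_items, replace=False))
        rows = (
            np.sort(rng.choice(m, size=n_feats, replace=False))
            if n_feats < m else slice(None)
        )
        sub = values[rows][:, cols]
        co_sample[np.ix_(cols, cols)] += 1
        link = linkage(sub.T, method="average", metric="euclidean")
        for k in ks:
            if k > len(cols):
                continue
            lab = fcluster(link, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_assign[k][np.ix_(cols, cols)] += same

    grid = np.linspace(0.0, 1.0, 101)
    consensus, labels, cdfs, areas = {}, {}, {}, {}
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in ks:
            mat = np.where(co_sample > 0, co_assign[k] / np.maximum(co_sample, 1), 0.0)
            mat = (mat + mat.T) / 2.0
            np.fill_diagonal(mat, 1.0)
            cons = pd.DataFrame(mat, index=samples, columns=samples)
            consensus[k] = cons
            final_link = linkage(squareform(1.0 - mat, checks=False), method="average")
            labels[k] = pd.Series(
                fcluster(final_link, t=k, criterion="maxclust"), index=samples
            )
            vals = mat[iu]
            cdfs[k] = np.array([(vals <= g).mean() for g in grid])
            areas[k] = float(np.trapezoid(cdfs[k], grid))

    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    return ConsensusResult(
        consensus=consensus, labels=labels, cdf_grid=grid,
        cdfs=cdfs, areas=areas, delta_area=delta,
    )


def assign_clusters(z_matrix: pd.DataFrame, k: int = 4, method: str = "ward",
                    consensus: ConsensusResult = None,
                    signature_rows=None) -> pd.Series:
    """Cluster samples and renumber labels by increasing mean methylation.

    ``method='ward'`` clusters the z-matrix columns directly (Euclidean,
    Ward linkage); ``method='consensus'`` cuts the consensus tree at k.
    Labels are renumbered so cluster 1 has the lowest mean value over
    ``signature_rows`` (default: all rows) — the "normal" end of the
    stepwise hypermethylation axis.
    """
    samples = list(z_matrix.columns)
    if k == 1:
        return pd.Series(1, index=samples)
    if method == "ward":
        link = linkage(z_matrix.to_numpy(dtype=float).T, method="ward",
                       metric="euclidean")
        raw = pd.Series(fcluster(link, t=k, criterion="maxclust"), index=samples)
    elif method == "consensus":
        if consensus is None or k not in consensus.labels:
            raise ValueError("consensus result with this k required")
        raw = consensus.labels[k].copy()
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = z_matrix.index if signature_rows is None else signature_rows
    means = z_matrix.loc[z_matrix.index.intersection(rows)].mean(axis=0)
    order = (
        means.groupby(raw).mean().sort_values().index.tolist()
    )  # raw labels ordered by mean methylation
    remap = {old: new for new, old in enumerate(order, start=1)}
    return raw.map(remap)


def pca_embed(z_matrix: pd.DataFrame, n_components: int = 2):
    """PCA of samples over features; returns (scores, explained fractions)."""
    X = z_matrix.to_numpy(dtype=float).T  # samples x features
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=z_matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
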