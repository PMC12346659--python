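"""EMT expression score, rank-based group comparisons, mutation burden,
and generic hypergeometric over-representation analysis (ORA).

The EMT score of a sample is the mean cohort z-score over an
epithelial-mesenchymal-transition gene panel (19 genes by default).
Group contrasts use Kruskal-Wallis overall plus pairwise two-sided
Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment, matching
standard practice for non-normal per-sample scores.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EMT_PANEL",
    "emt_score",
    "compare_groups",
    "mutation_burden",
    "ora_hypergeometric",
]

# 19-gene epithelial-mesenchymal-transition panel
EMT_PANEL = (
    "ITGB1", "VIM", "MMP2", "COL1A1", "TWIST1", "CTNNB1", "SNAI1",
    "FN1", "SNAI2", "TGFB1", "ITGB6", "SOX10", "CDH1", "CDH2",
    "MMP9", "TWIST2", "ZEB1", "ZEB2", "FOXC2",
)


def emt_score(expression: pd.DataFrame, panel: Sequence[str] = EMT_PANEL):
    """Per-sample mean cohort z-score over the panel genes.

    ``expression``: genes x samples, already on log scale.  Per gene the
    z-score uses the cohort mean and sample SD (ddof=1) across all
    samples.  Genes absent from the matrix or with zero SD are skipped
    and reported; an error is raised when no panel gene is scoreable.

    Returns (scores Series, skipped gene list).
    """
    present = [g for g in panel if g in expression.index]
    skipped = [g for g in panel if g not in expression.index]
    sub = expression.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    constant = sd[sd == 0].index.tolist()
    skipped.extend(constant)
    usable = sub.drop(index=constant)
    if usable.empty:
        raise ValueError("no scoreable EMT panel gene (all missing or constant)")
    z = usable.sub(usable.mean(axis=1), axis=0).div(
        usable.std(axis=1, ddof=1), axis=0
    )
    return z.mean(axis=0), skipped


def _ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum: exact for n<=10 without ties, else
    normal approximation with continuity and tie correction."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    if max(len(x), len(y)) <= 10 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def compare_groups(values, labels, pairwise: bool = True, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis across groups + pairwise BH-adjusted rank-sum tests.

    Returns dict with ``kw_statistic``, ``kw_p`` and (when requested) a
    ``pairwise`` DataFrame with raw and BH-adjusted p-values and a
    significance flag at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    arrays = [values[labels == g] for g in groups]
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    if all(np.array_equal(a, arrays[0]) for a in arrays) or \
            len(np.unique(values)) == 1:
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*arrays)
    result = {"kw_statistic": float(kw_stat), "kw_p": float(kw_p),
              "groups": groups}
    if pairwise:
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                p = _ranksum_pvalue(arrays[i], arrays[j])
                rows.append({"group_a": groups[i], "group_b": groups[j], "p": p})
        table = pd.DataFrame(rows)
        if not table.empty:
            table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
            table["significant"] = table["p_adj"] < alpha
        result["pairwise"] = table
    return result


def mutation_burden(source, labels: Optional[dict] = None,
                    pairwise: bool = True) -> dict:
    """Per-sample mutation totals, optionally compared across clusters.

    ``source``: list of ClinicalRecords with ``mutation_count`` or a
    binary gene x sample DataFrame (totals = column sums).
    """
    if isinstance(source, pd.DataFrame):
        totals = source.sum(axis=0).astype(float)
    else:
        totals = pd.Series(
            {r.sample_id: np.nan if r.mutation_count is None else float(r.mutation_count)
             for r in source}
        )
    out = {"totals": totals}
    if labels is not None:
        keep = totals.dropna().index.intersection(pd.Index(labels.keys()))
        out["comparison"] = compare_groups(
            totals.loc[keep].to_numpy(),
            np.array([labels[s] for s in keep]),
            pairwise=pairwise,
        )
    return out


def ora_hypergeometric(query, universe, gene_sets) -> pd.DataFrame:
    """Over-representation by upper-tail hypergeometric test + BH.

    p = P(X >= overlap) with X ~ Hypergeom(universe, set∩universe,
    |query|).  Sets are intersected with the universe before testing;
    the query must be a subset of the universe.
    """
    query, universe = set(query), set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        n = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({
            "set": name, "overlap": k, "set_size": n,
            "universe_size": M, "query_size": N, "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p_adj", "p", "set"]).reset_index(drop=True)
    return df
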