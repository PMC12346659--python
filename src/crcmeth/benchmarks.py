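"""Reference benchmarks: worked-example arithmetic, oracle-equivalence
sweeps, planted-structure recovery, and statistical calibration.

These functions re-run the pipeline end to end under the study
conditions encoded in :class:`~crcmeth.synthetic.SimulationConfig` and
return plain numbers; the acceptance script and the corresponding tests
both call them.
"""

from __future__ import annotations

import itertools
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .binmatrix import zscore_rows
from .cimp import OGINO, call_gene_methylation, classify_cimp, summary_from_counts
from .cluster import assign_clusters
from .dmr import call_dmrs_tiles, tile_counts
from .evaluate import (
    adjusted_rand_index,
    design_from_samples,
    dmr_recovery,
    run_consensus_pipeline,
)
from .network import centrality
from .scores import ora_hypergeometric
from .survival import logrank_test
from .synthetic import SimulationConfig, simulate_beta_matrix, simulate_count_data

# ---------------------------------------------------------------------------
# CIMP worked-example arithmetic (published tumor-only counts as inputs)
# ---------------------------------------------------------------------------

# TCGA COAD-READ tumor-only label counts (inputs to the summary operation)
WEISENBERGER_COUNTS = (37, 111, 262)  # CIMP-H, CIMP-L, CIMP-N
OGINO_COUNTS = (31, 74, 305)
N_NORMALS = 45  # 455 total samples - 410 tumors


def cimp_published_summary() -> dict:
    """Summary percentages / with-normals totals from the printed counts."""
    return {
        "weisenberger": summary_from_counts(*WEISENBERGER_COUNTS, N_NORMALS),
        "ogino": summary_from_counts(*OGINO_COUNTS, N_NORMALS),
    }


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def _fisher_two_sided_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher p by summing hypergeometric point masses not
    exceeding the observed one (integer combinatorics)."""
    n1, n2, k = a + b, c + d, a + c
    total = math.comb(n1 + n2, k)
    obs = math.comb(n1, a) * math.comb(n2, c)
    acc = 0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        mass = math.comb(n1, x) * math.comb(n2, k - x)
        if mass <= obs * (1 + 1e-9):
            acc += mass
    return acc / total


def fisher_oracle_check(max_margin: int = 30) -> dict:
    """Max |implementation - enumeration| over all 2x2 tables with both
    group margins in [1, max_margin]."""
    worst = 0.0
    count = 0
    for n1 in range(1, max_margin + 1):
        for n2 in range(1, max_margin + 1):
            for a in range(n1 + 1):
                for c in range(n2 + 1):
                    p_impl = stats.fisher_exact(
                        [[a, n1 - a], [c, n2 - c]], alternative="two-sided"
                    )[1]
                    p_oracle = _fisher_two_sided_enumeration(a, n1 - a, c, n2 - c)
                    worst = max(worst, abs(p_impl - p_oracle))
                    count += 1
    return {"max_abs_diff": worst, "n_tables": count}


def ora_oracle_check(max_margin: int = 25) -> dict:
    """Max |ORA p - combinatorial tail sum| over hypergeometric margins
    up to max_margin."""
    worst = 0.0
    count = 0
    for M in range(1, max_margin + 1):
        universe = [f"g{i}" for i in range(M)]
        for N in range(0, M + 1):
            if N == 0:
                continue
            query = universe[:N]
            sets = {}
            expected = {}
            for n in range(1, M + 1):
                for k in range(max(0, n - (M - N)), min(n, N) + 1):
                    name = f"n{n}k{k}"
                    sets[name] = universe[:k] + universe[N:N + (n - k)]
                    if len(sets[name]) != n:
                        del sets[name]
                        continue
                    total = math.comb(M, N)
                    tail = sum(
                        math.comb(n, x) * math.comb(M - n, N - x)
                        for x in range(k, min(n, N) + 1)
                    )
                    expected[name] = tail / total
            if not sets:
                continue
            result = ora_hypergeometric(query, universe, sets).set_index("set")
            for name, exp in expected.items():
                diff = abs(result.loc[name, "p"] - exp)
                worst = max(worst, diff)
                count += 1
    return {"max_abs_diff": worst, "n_tests": count}


def _brute_force_centralities(graph):
    """All-pairs shortest-path enumeration for graphs with <= 8 nodes."""
    nodes = list(graph.nodes)
    n = len(nodes)
    dist, through = {}, {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        best, paths = None, []
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                if best is None or len(path) - 1 < best:
                    best, paths = len(path) - 1, [path]
                elif len(path) - 1 == best:
                    paths.append(path)
                continue
            if best is not None and len(path) - 1 >= best:
                continue
            for w in graph[u]:
                if w not in path:
                    stack.append((w, path + [w]))
        if best is None:
            continue
        dist[(s, t)] = dist[(t, s)] = best
        for v in nodes:
            if v not in (s, t):
                through[v] += sum(1 for p in paths if v in p) / len(paths)
    betweenness = {
        v: through[v] / ((n - 1) * (n - 2) / 2) if n > 2 else 0.0 for v in nodes
    }
    closeness = {
        v: (
            sum(1.0 / dist[(v, u)] for u in nodes if u != v and (v, u) in dist)
            / (n - 1) if n > 1 else 0.0
        )
        for v in nodes
    }
    return betweenness, closeness


def centrality_oracle_check(n_graphs: int = 100, max_nodes: int = 8,
                            seed: int = 0) -> dict:
    """Max centrality deviation from path enumeration over random graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.95),
                                seed=int(rng.integers(2**31)))
        cent = centrality(g)
        bet, close = _brute_force_centralities(g)
        for v in g.nodes:
            worst = max(worst, abs(cent.loc[v, "betweenness"] - bet[v]))
            worst = max(worst, abs(cent.loc[v, "closeness"] - close[v]))
    return {"max_abs_diff": worst, "n_graphs": n_graphs}


# ---------------------------------------------------------------------------
# planted-structure recovery
# ---------------------------------------------------------------------------

def consensus_recovery_benchmark(n_seeds: int = 20, seed0: int = 0) -> dict:
    """Consensus-caller recall/precision against planted DMRs
    (effect 0.4, coverage 30, 6 vs 6 samples), seed-averaged."""
    recalls, precisions = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            config = SimulationConfig(seed=seed0 + i, n_samples_per_group=(6, 6))
            records, truth = simulate_count_data(config)
            result = run_consensus_pipeline(records)
            metrics = dmr_recovery(result["consensus"], truth.planted_dmrs)
            recalls.append(metrics["recall"])
            precisions.append(metrics["precision"])
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.nanmean(precisions)),
        "n_seeds": n_seeds,
    }


def ward_clustering_benchmark(seed: int = 0) -> dict:
    """Ward ARI vs planted 4-cluster truth (shifts 0/.15/.25/.40,
    noise .05, 40/cluster) and whether renumbering follows shift order."""
    config = SimulationConfig(seed=seed)
    beta, _, truth = simulate_beta_matrix(config)
    z, _ = zscore_rows(beta[truth.cluster_labels.index])
    labels = assign_clusters(z, k=4, method="ward",
                             signature_rows=truth.signature_probes)
    ari = adjusted_rand_index(truth.cluster_labels, labels)
    table = pd.crosstab(truth.cluster_labels, labels)
    order_ok = bool(
        (table.idxmax(axis=1).to_numpy() == table.index.to_numpy()).all()
    )
    return {"ari": ari, "order_matches_shifts": order_ok}


def cimp_recovery_benchmark(seed: int = 0, n_samples: int = 40,
                            n_planted: int = 6) -> dict:
    """Fraction of runs where a +5 Z-shift on all panel probes recovers
    the planted CIMP-H sample set exactly (1.0 = exact)."""
    rng = np.random.default_rng(seed)
    probes = [f"{g}_p{i}" for g in OGINO.genes for i in range(3)]
    mapping = {p: p.rsplit("_", 1)[0] for p in probes}
    samples = [f"s{i}" for i in range(n_samples)]
    z = pd.DataFrame(rng.normal(0.0, 1.0, (len(probes), n_samples)),
                     index=probes, columns=samples)
    planted = set(rng.choice(samples, size=n_planted, replace=False))
    z[list(planted)] += 5.0
    calls = classify_cimp(call_gene_methylation(z, mapping), OGINO)
    called = {c.sample_id for c in calls if c.label == "CIMP-H"}
    return {"exact_recovery": 1.0 if called == planted else 0.0,
            "n_planted": n_planted}


# ---------------------------------------------------------------------------
# statistical calibration
# ---------------------------------------------------------------------------

def logrank_type1_error(n_reps: int = 1000, n_per_arm: int = 50,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the two-group log-rank under equal exponential
    hazards (no planted difference)."""
    rng = np.random.default_rng(seed)
    groups = np.array(["a"] * n_per_arm + ["b"] * n_per_arm)
    rejections = 0
    for _ in range(n_reps):
        times = rng.exponential(500.0, size=2 * n_per_arm)
        events = np.ones(2 * n_per_arm, dtype=int)
        res = logrank_test(times, events, groups)
        rejections += res.p_value < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps}


def kruskal_type1_error(n_reps: int = 1000, n_per_group: int = 20,
                        n_groups: int = 3, alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Rejection rate of Kruskal-Wallis under exchangeable groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        arrays = [rng.normal(0, 1, n_per_group) for _ in range(n_groups)]
        rejections += stats.kruskal(*arrays).pvalue < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps}


def null_tile_discovery(n_seeds: int = 50, seed0: int = 1000) -> dict:
    """Fraction of tested tiles passing q<0.01 and |diff|>=25 when no
    DMR is planted (effect_delta = 0)."""
    significant = tested = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            config = SimulationConfig(seed=seed0 + i,
                                      n_samples_per_group=(6, 6),
                                      effect_delta=0.0)
            records, _ = simulate_count_data(config)
            design = design_from_samples(records)
            tiled = tile_counts(records)
            hits = call_dmrs_tiles(tiled, design)
            significant += len(hits)
            tested += len(tiled)
    return {"fraction": significant / tested if tested else 0.0,
            "n_seeds": n_seeds, "n_tiles_tested": tested}
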