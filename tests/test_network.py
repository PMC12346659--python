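import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crcmeth.network import (
    build_network,
    centrality,
    hub_regulatory_sign,
    identify_hubs,
    infer_tf_activity,
)


def regulons(rows):
    return pd.DataFrame(rows, columns=["tf", "target", "mode"])


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def test_activator_activity_is_mean_target_z():
    z = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=["g1", "g2", "g3"])
    regs = regulons([("TF", f"g{i}", 1) for i in (1, 2, 3)])
    activity, excluded, n_used = infer_tf_activity(z, regs)
    assert activity.loc["TF", "s1"] == pytest.approx(1.0)
    assert excluded == [] and n_used["TF"] == 3


def test_repressor_sign_convention():
    z = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=["g1", "g2", "g3"])
    regs = regulons([("TF", f"g{i}", -1) for i in (1, 2, 3)])
    activity, _, _ = infer_tf_activity(z, regs)
    assert activity.loc["TF", "s1"] == pytest.approx(-1.0)


def test_tf_with_few_targets_excluded():
    z = pd.DataFrame({"s1": [1.0, 1.0]}, index=["g1", "g2"])
    regs = regulons([("TF", "g1", 1), ("TF", "g2", 1), ("TF", "g_absent", 1)])
    activity, excluded, _ = infer_tf_activity(z, regs)
    assert excluded == ["TF"] and activity.empty


def test_planted_activity_recovered():
    rng = np.random.default_rng(6)
    targets = [f"g{i}" for i in range(30)]
    regs = regulons([("TF", g, 1) for g in targets])
    samples = [f"s{i}" for i in range(50)]
    z = pd.DataFrame(
        2.0 + rng.normal(0, 0.5, (30, 50)), index=targets, columns=samples
    )
    activity, _, _ = infer_tf_activity(z, regs)
    assert activity.loc["TF"].mean() == pytest.approx(2.0, abs=0.3)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def test_identical_profiles_edge_weight_one():
    profiles = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]], index=["a", "b"]
    )
    g = build_network(profiles)
    assert g["a"]["b"]["weight"] == pytest.approx(1.0)
    assert g["a"]["b"]["sign"] == 1


def test_anticorrelated_edge_sign():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    noise = np.array([0.1, -0.2, 0.15, -0.05, 0.0])
    profiles = pd.DataFrame([x, -x + noise], index=["a", "b"])
    g = build_network(profiles, threshold=0.4)
    assert g["a"]["b"]["sign"] == -1


def test_threshold_pruning_monotone(rng):
    profiles = pd.DataFrame(rng.normal(0, 1, (15, 30)))
    edges = [
        set(build_network(profiles, threshold=t).edges())
        for t in (0.2, 0.4, 0.6, 0.8)
    ]
    for lower, higher in zip(edges, edges[1:]):
        assert higher <= lower


def test_null_profiles_rarely_connected(rng):
    profiles = pd.DataFrame(rng.normal(0, 1, (30, 200)))
    g = build_network(profiles, threshold=0.4)
    possible = 30 * 29 / 2
    assert g.number_of_edges() / possible < 0.01  # |r|>=0.4 at n=200 is rare


def test_no_self_edges(rng):
    profiles = pd.DataFrame(rng.normal(0, 1, (10, 20)))
    g = build_network(profiles, threshold=0.1)
    assert all(u != v for u, v in g.edges())


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def brute_force_centralities(graph):
    """All-pairs shortest-path enumeration (BFS-free, <=8 nodes)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    dist, n_paths, through = {}, {}, {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        best, paths = None, []
        # enumerate all simple paths
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
        n_paths[(s, t)] = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through_count = sum(1 for p in paths if v in p)
            through[v] += through_count / len(paths)
    betweenness = {
        v: through[v] / ((n - 1) * (n - 2) / 2) if n > 2 else 0.0 for v in nodes
    }
    closeness = {
        v: sum(
            1.0 / dist[(v, u)] for u in nodes if u != v and (v, u) in dist
        ) / (n - 1) if n > 1 else 0.0
        for v in nodes
    }
    return betweenness, closeness


def test_path_graph_centralities():
    g = nx.path_graph(["A", "B", "C"])
    cent = centrality(g)
    assert cent.loc["B", "degree"] == 2
    assert cent.loc["B", "betweenness"] == pytest.approx(1.0)
    assert cent.loc["A", "betweenness"] == pytest.approx(0.0)
    assert cent.loc["B", "closeness"] == pytest.approx(1.0)
    assert cent.loc["A", "closeness"] == pytest.approx((1 + 0.5) / 2)


def test_complete_graph_zero_betweenness():
    cent = centrality(nx.complete_graph(5))
    assert (cent["betweenness"] == 0).all()
    assert (cent["degree"] == 4).all()


def test_star_graph_center():
    g = nx.star_graph(4)  # center 0, leaves 1..4
    cent = centrality(g)
    assert cent.loc[0, "degree"] == 4
    assert (cent.loc[1:, "degree"] == 1).all()
    flags = identify_hubs(cent)
    assert flags.loc[0, "hub"] and flags.loc[0, "bottleneck"]
    assert not flags.loc[1:, "hub"].any()


def test_centralities_match_brute_force_enumeration(rng):
    for _ in range(25):
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9),
                                seed=int(rng.integers(2**31)))
        cent = centrality(g)
        bet, close = brute_force_centralities(g)
        for v in g.nodes:
            assert cent.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-10)
            assert cent.loc[v, "closeness"] == pytest.approx(close[v], abs=1e-10)


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def test_equal_degrees_all_tied_flagged():
    cent = centrality(nx.cycle_graph(6))  # all degrees 2
    flags = identify_hubs(cent)
    assert flags["hub"].all()  # ties at the quantile take the flag


def test_empty_graph_no_flags():
    flags = identify_hubs(centrality(nx.Graph()))
    assert flags.empty


def test_hub_regulatory_sign():
    rng = np.random.default_rng(2)
    activity = pd.Series(rng.normal(0, 1, 40), index=[f"s{i}" for i in range(40)])
    up = activity + rng.normal(0, 0.3, 40)
    down = -activity + rng.normal(0, 0.3, 40)
    z = pd.DataFrame(
        [up.to_numpy(), up.to_numpy(), down.to_numpy(), down.to_numpy()],
        index=["u1", "u2", "d1", "d2"], columns=activity.index,
    )
    regs_up = regulons([("TF", "u1", 1), ("TF", "u2", 1)])
    regs_down = regulons([("TF", "d1", 1), ("TF", "d2", 1)])
    assert hub_regulatory_sign("TF", activity, z, regs_up) == 1
    assert hub_regulatory_sign("TF", activity, z, regs_down) == -1
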