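"""Weighted network construction, Girvan–Newman communities, modularity."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from trajnet.fluctuations import CorrelationMatrix
from trajnet.io import Node, NodeSet
from trajnet.network import (
    CORRELATION_FLOOR,
    analyze_ensemble,
    build_network,
    community_graph,
    edge_betweenness,
    girvan_newman,
    half_trajectory_convergence,
    modularity,
)


def _nodes(n):
    return NodeSet([Node("A", i + 1, " ", "protein", i) for i in range(n)])


def _corr(n, value=math.exp(-1.0)):
    c = np.full((n, n), value)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c, _nodes(n))


def network_from_edges(edges, n=None, c=math.exp(-1.0)):
    """Uniform-|c| network: weighted and unweighted betweenness coincide."""
    if n is None:
        n = max(max(e) for e in edges) + 1
    return build_network(list(edges), _corr(n, c))


# ---------------------------------------------------------------------------
# exhaustive modularity oracle

def _set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(graph):
    best_q, best_labels = -np.inf, None
    nodes = sorted(graph.nodes)
    for part in _set_partitions(nodes):
        labels = {v: k for k, block in enumerate(part) for v in block}
        q = modularity(labels, graph)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return best_q, best_labels


# ---------------------------------------------------------------------------
# edge weights

def test_edge_weight_formula_spot_values(caplog):
    edges = [(0, 1), (1, 2), (2, 3)]
    c = np.eye(4)
    for (i, j), v in zip(edges, (1.0, 0.5, 0.0)):
        c[i, j] = c[j, i] = v
    with caplog.at_level("WARNING"):
        net = build_network(edges, CorrelationMatrix(c, _nodes(4)))
    w = {tuple(sorted(e)): d["w"] for *e, d in net.graph.edges(data=True)}
    assert w[(0, 1)] == pytest.approx(0.0, abs=1e-4)
    assert w[(1, 2)] == pytest.approx(math.log(2.0), abs=1e-4)
    assert w[(2, 3)] == pytest.approx(-math.log(CORRELATION_FLOOR), abs=1e-4)
    assert any("floor" in r.message for r in caplog.records)


def test_missing_correlation_entry_is_an_error():
    c = np.eye(3)
    c[0, 1] = c[1, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        build_network([(0, 1)], CorrelationMatrix(c, _nodes(3)))
    with pytest.raises(ValueError, match="missing"):
        build_network([(0, 5)], CorrelationMatrix(np.eye(3), _nodes(3)))


# ---------------------------------------------------------------------------
# betweenness

def test_bridge_between_triangles_has_betweenness_nine(two_triangle_edges):
    net = network_from_edges(two_triangle_edges)
    bt = edge_betweenness(net, weighted=False)
    # 15 node pairs; the 9 cross pairs each route over the bridge once
    assert bt[(2, 3)] == pytest.approx(9.0)
    bt_w = edge_betweenness(net, weighted=True)  # uniform weights: identical
    assert bt_w[(2, 3)] == pytest.approx(9.0)


def test_path_graph_betweenness_by_hand():
    net = network_from_edges([(0, 1), (1, 2)])
    bt = edge_betweenness(net, weighted=False)
    assert bt[(0, 1)] == pytest.approx(2.0)  # pairs (0,1) and (0,2)
    assert bt[(1, 2)] == pytest.approx(2.0)


def test_symmetric_square_has_equal_betweenness_on_all_edges():
    net = network_from_edges([(0, 1), (1, 2), (2, 3), (3, 0)])
    bt = edge_betweenness(net, weighted=True)
    values = list(bt.values())
    assert np.allclose(values, values[0])


# ---------------------------------------------------------------------------
# modularity

def test_single_community_has_zero_modularity(two_triangle_edges):
    g = nx.Graph(two_triangle_edges)
    assert modularity({v: 0 for v in g.nodes}, g) == pytest.approx(0.0)


def test_two_triangle_partition_matches_hand_formula(two_triangle_edges):
    g = nx.Graph(two_triangle_edges)
    labels = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    # m = 7; e_kk = 3/7 each; a_k = 1/2 each: Q = 6/7 - 1/2 = 0.357142...
    assert modularity(labels, g) == pytest.approx(5.0 / 14.0, abs=1e-12)


def test_singleton_partition_of_k4_is_negative():
    g = nx.complete_graph(4)
    labels = {v: v for v in g.nodes}
    # e_kk = 0, each a_k = 3/12: Q = -4 (1/4)^2 = -0.25
    assert modularity(labels, g) == pytest.approx(-0.25, abs=1e-12)


def test_missing_label_raises():
    g = nx.Graph([(0, 1)])
    with pytest.raises(ValueError, match="missing"):
        modularity({0: 0}, g)


# ---------------------------------------------------------------------------
# Girvan–Newman

def test_two_triangles_split_at_the_bridge(two_triangle_edges):
    net = network_from_edges(two_triangle_edges)
    part = girvan_newman(net)
    assert part.n_communities == 2
    assert part.q == pytest.approx(5.0 / 14.0, abs=1e-4)
    groups = {}
    for v, k in part.labels.items():
        groups.setdefault(k, set()).add(v)
    assert sorted(groups.values(), key=min) == [{0, 1, 2}, {3, 4, 5}]
    # bridge removed first: step 1 of the trace already shows 2 communities
    assert part.q_trace[1][1] == 2


def test_complete_graph_stays_one_community():
    net = network_from_edges(list(itertools.combinations(range(4), 2)))
    part = girvan_newman(net)
    assert part.n_communities == 1
    assert part.q == pytest.approx(0.0, abs=1e-12)
    assert part.q_trace[0] == (0, 1, 0.0)  # returned at step 0 (earliest tie)


def test_returned_q_equals_recomputed_modularity(two_triangle_edges):
    net = network_from_edges(two_triangle_edges)
    part = girvan_newman(net)
    assert part.q == pytest.approx(
        modularity(part.labels, net.unweighted()), abs=1e-12
    )


def test_girvan_newman_is_deterministic(two_triangle_edges):
    net = network_from_edges(two_triangle_edges)
    p1 = girvan_newman(net)
    p2 = girvan_newman(net)
    assert p1.labels == p2.labels
    assert p1.q_trace == p2.q_trace


def test_edgeless_graph_yields_singletons_with_zero_q(caplog):
    net = build_network([], _corr(4))
    with caplog.at_level("WARNING"):
        part = girvan_newman(net)
    assert part.n_communities == 4
    assert part.q == 0.0


@pytest.mark.parametrize(
    "edges",
    [
        [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)],  # triangles
        list(itertools.combinations(range(4), 2)),                  # K4
        [(0, 1), (1, 2), (2, 3), (3, 4)],                           # path P5
        [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)],           # cycle C6
        [(0, i) for i in range(1, 6)],                              # star S5
        # two squares joined by a bridge (8 nodes)
        [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4), (3, 4)],
    ],
)
def test_best_q_partition_matches_exhaustive_search(edges):
    """On every ≤8-node fixture the GN best-Q cut attains the global
    maximum-modularity partition value."""
    net = network_from_edges(edges)
    part = girvan_newman(net)
    best_q, _ = exhaustive_best_modularity(net.unweighted())
    assert part.q == pytest.approx(best_q, abs=1e-9)


# ---------------------------------------------------------------------------
# community graph

def test_community_pair_edge_carries_cumulative_betweenness(two_triangle_edges):
    net = network_from_edges(two_triangle_edges)
    part = girvan_newman(net)
    cg = community_graph(net, part, weighted=False)
    assert cg.graph.number_of_edges() == 1
    (a, b, data), = cg.graph.edges(data=True)
    assert data["weight"] == pytest.approx(9.0)
    sizes = nx.get_node_attributes(cg.graph, "size")
    assert sorted(sizes.values()) == [3, 3]


def test_single_community_gives_no_edges():
    net = network_from_edges(list(itertools.combinations(range(4), 2)))
    part = girvan_newman(net)
    cg = community_graph(net, part)
    assert cg.graph.number_of_edges() == 0


def test_three_blocks_in_a_chain_give_a_path_community_graph():
    tri = lambda o: [(o, o + 1), (o, o + 2), (o + 1, o + 2)]
    edges = tri(0) + tri(3) + tri(6) + [(2, 3), (5, 6)]
    net = network_from_edges(edges)
    part = girvan_newman(net)
    assert part.n_communities == 3
    cg = community_graph(net, part)
    degrees = sorted(d for _, d in cg.graph.degree)
    assert degrees == [1, 1, 2]  # a 3-node path


# ---------------------------------------------------------------------------
# pipeline-level checks

def test_identical_halves_agree_perfectly():
    from trajnet.synthetic import SyntheticSpec, sample_ensemble
    from trajnet.io import TrajectoryEnsemble

    ens, _ = sample_ensemble(
        SyntheticSpec(blocks=(8, 8), n_frames=200, seed=2)
    )
    doubled = TrajectoryEnsemble(
        ens.topology, np.concatenate([ens.frames, ens.frames])
    )
    report = half_trajectory_convergence(doubled)
    assert report.ari == pytest.approx(1.0)
    assert report.q_first == pytest.approx(report.q_second)


def test_white_noise_on_sparse_geometry_still_reports():
    """Independent white-noise halves with no persistent contacts must not
    crash the convergence report."""
    from conftest import bead_model
    from trajnet.io import TrajectoryEnsemble

    rng = np.random.default_rng(0)
    model = bead_model(
        rng.uniform(0, 100, size=(6, 3)),
        chains=list("ABCDEF"), resseqs=[1] * 6,
    )
    frames = model.coords[None] + rng.normal(0, 0.5, size=(40, 6, 3))
    report = half_trajectory_convergence(TrajectoryEnsemble(model, frames))
    assert report.n_communities_first == 6  # all singletons, edgeless
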