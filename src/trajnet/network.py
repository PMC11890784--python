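"""Correlation-weighted contact networks and dynamic communities.

Network nodes are residues (Cα/P beads); edges are the persistent contacts,
weighted by

    w_ij = −ln(max(|c_ij|, ε)),   ε = 1e−6,

so strongly correlated residue pairs are connected by short edges. The
network is partitioned by the Girvan–Newman procedure: the edge of highest
betweenness is removed repeatedly (betweenness recomputed after every
removal), the modularity Q of the resulting connected components is tracked
on the original unweighted contact graph, and the partition with maximal Q
over the whole removal trace is returned — the full Q-trace is exposed so a
modularity plateau can be inspected. Inter-community communication is
summarized by the cumulative betweenness of inter-community edges.

Betweenness used for edge removal follows weighted shortest paths (w as edge
length) by default; modularity is always computed on the unweighted contact
graph. Both conventions are recorded in result metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .contacts import (
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_PERSISTENCE_THRESHOLD,
    contact_edges,
    contact_persistence,
)
from .fluctuations import CorrelationMatrix, correlation_matrix, superpose
from .io import NodeSet, TrajectoryEnsemble, select_nodes

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicNetwork",
    "CommunityPartition",
    "CommunityGraph",
    "ConvergenceReport",
    "CORRELATION_FLOOR",
    "build_network",
    "edge_betweenness",
    "girvan_newman",
    "modularity",
    "community_graph",
    "analyze_ensemble",
    "half_trajectory_convergence",
]

CORRELATION_FLOOR = 1e-6  # caps w at −ln(1e−6) ≈ 13.8155


@dataclass
class DynamicNetwork:
    """Contact-restricted weighted graph over a NodeSet."""

    graph: nx.Graph
    nodes: NodeSet

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def unweighted(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(self.graph.edges)
        return g

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for i in self.graph.nodes:
            g.add_node(i, label=self.nodes[i].label)
        for i, j, data in self.graph.edges(data=True):
            g.add_edge(i, j, w=float(data["w"]), c=float(data["c"]))
        nx.write_graphml(g, path)

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {"id": int(i), "label": self.nodes[i].label}
                for i in self.graph.nodes
            ],
            "edges": [
                {"i": int(i), "j": int(j), "w": float(d["w"]), "c": float(d["c"])}
                for i, j, d in self.graph.edges(data=True)
            ],
        }


@dataclass
class CommunityPartition:
    """Node→community labels with the modularity trace of the GN removals."""

    labels: dict[int, int]
    q: float
    q_trace: list[tuple[int, int, float]]  # (step, n_communities, Q)
    dendrogram: list[tuple[int, tuple[frozenset, ...]]]  # split steps
    metadata: dict = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def labels_array(self, n: int | None = None) -> np.ndarray:
        n = len(self.labels) if n is None else n
        return np.array([self.labels[i] for i in range(n)], dtype=int)

    def write_table(self, nodes: NodeSet, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tcommunity\n")
            for i, node in enumerate(nodes):
                fh.write(f"{node.label}\t{self.labels[i]}\n")

    def write_q_trace(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step,n_communities,Q\n")
            for step, k, q in self.q_trace:
                fh.write(f"{step},{k},{q:.6f}\n")


@dataclass
class CommunityGraph:
    """Communities as nodes, cumulative inter-community betweenness as edges."""

    graph: nx.Graph  # node attr "size"; edge attr "weight"

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {"id": int(c), "size": int(d["size"])}
                for c, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {"a": int(a), "b": int(b), "weight": float(d["weight"])}
                for a, b, d in self.graph.edges(data=True)
            ],
        }


# ---------------------------------------------------------------------------
# construction

def build_network(
    edges: list[tuple[int, int]],
    corr: CorrelationMatrix,
    floor: float = CORRELATION_FLOOR,
) -> DynamicNetwork:
    """Weight contact edges by w = −ln(max(|c|, floor)).

    |c| below the floor is floored with a warning (which caps w ≈ 13.82 at
    the default floor).
    """
    n = len(corr.nodes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    floored = 0
    for i, j in edges:
        if i == j:
            continue
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"contact pair ({i}, {j}) missing from correlation matrix")
        c = float(corr.c[i, j])
        if not np.isfinite(c):
            raise ValueError(f"contact pair ({i}, {j}) missing from correlation matrix")
        a = abs(c)
        if a < floor:
            a = floor
            floored += 1
        g.add_edge(i, j, w=float(-np.log(a)), c=c)
    if floored:
        logger.warning(
            "|c| below floor %.1e on %d edge(s); weights capped at %.4f",
            floor, floored, -np.log(floor),
        )
    return DynamicNetwork(g, corr.nodes)


def edge_betweenness(
    network: DynamicNetwork | nx.Graph, weighted: bool = True
) -> dict[tuple[int, int], float]:
    """Brandes edge betweenness; each unordered node pair counted once."""
    g = network.graph if isinstance(network, DynamicNetwork) else network
    if weighted:
        for _, _, d in g.edges(data=True):
            if d.get("w", 0.0) < 0:
                raise ValueError("negative edge weight")
    bt = nx.edge_betweenness_centrality(
        g, normalized=False, weight="w" if weighted else None
    )
    return {(min(i, j), max(i, j)): v for (i, j), v in bt.items()}


# ---------------------------------------------------------------------------
# modularity and Girvan–Newman

def modularity(labels: dict[int, int], graph: nx.Graph) -> float:
    """Newman modularity Q = Σ_k (e_kk − a_k²) on an unweighted graph."""
    m = graph.number_of_edges()
    if m == 0:
        logger.warning("modularity of an edgeless graph defined as 0")
        return 0.0
    for v in graph.nodes:
        if v not in labels:
            raise ValueError(f"node {v} missing from partition labels")
    e_kk: dict[int, int] = {}
    deg: dict[int, int] = {}
    for i, j in graph.edges:
        if labels[i] == labels[j]:
            e_kk[labels[i]] = e_kk.get(labels[i], 0) + 1
    for v, d in graph.degree:
        deg[labels[v]] = deg.get(labels[v], 0) + d
    return sum(
        e_kk.get(k, 0) / m - (deg.get(k, 0) / (2.0 * m)) ** 2
        for k in set(labels[v] for v in graph.nodes)
    )


def _component_labels(g: nx.Graph) -> tuple[dict[int, int], tuple[frozenset, ...]]:
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda s: min(s),
    )
    labels = {v: k for k, comp in enumerate(comps) for v in comp}
    return labels, tuple(comps)


def girvan_newman(
    network: DynamicNetwork, weighted: bool = True
) -> CommunityPartition:
    """Betweenness-driven divisive community detection.

    Removes the highest-betweenness edge (ties broken toward the smallest
    (i, j) pair), recomputing betweenness after every removal, until no edge
    remains. After each removal the connected components and their modularity
    on the ORIGINAL unweighted contact graph are recorded; the partition with
    maximal Q is returned (ties → earliest step), with the full Q-trace and
    the dendrogram of splits attached.
    """
    base = network.unweighted()
    work = network.graph.copy()
    if base.number_of_edges() == 0:
        logger.warning("edgeless network: every node is its own community, Q = 0")
        labels = {v: k for k, v in enumerate(sorted(base.nodes))}
        return CommunityPartition(
            labels, 0.0, [(0, len(labels), 0.0)],
            [(0, tuple(frozenset([v]) for v in sorted(base.nodes)))],
            metadata=_metadata(weighted),
        )

    labels, comps = _component_labels(work)
    q = modularity(labels, base)
    q_trace = [(0, len(comps), q)]
    dendrogram = [(0, comps)]
    best = (q, 0, labels)
    step = 0
    prev_ncomp = len(comps)
    while work.number_of_edges() > 0:
        step += 1
        bt = edge_betweenness(work, weighted=weighted)
        target = max(
            bt.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1])
        )[0]
        work.remove_edge(*target)
        labels, comps = _component_labels(work)
        q = modularity(labels, base)
        q_trace.append((step, len(comps), q))
        if len(comps) > prev_ncomp:
            dendrogram.append((step, comps))
            prev_ncomp = len(comps)
        if q > best[0] + 1e-12:
            best = (q, step, labels)
    return CommunityPartition(
        best[2], best[0], q_trace, dendrogram, metadata=_metadata(weighted)
    )


def _metadata(weighted: bool) -> dict:
    return {
        "betweenness_weighted": bool(weighted),
        "modularity_graph": "unweighted_contact_graph",
        "correlation_floor": CORRELATION_FLOOR,
        "tie_break": "lexicographic_smallest_edge",
        "plateau_rule": "global_max_Q_over_trace",
    }


def community_graph(
    network: DynamicNetwork,
    partition: CommunityPartition,
    weighted: bool = True,
) -> CommunityGraph:
    """Coarse-grain graph: community sizes and cumulative inter-community
    betweenness of the original network's edges."""
    bt = edge_betweenness(network, weighted=weighted)
    g = nx.Graph()
    sizes: dict[int, int] = {}
    for v, k in partition.labels.items():
        sizes[k] = sizes.get(k, 0) + 1
    for k, s in sorted(sizes.items()):
        g.add_node(k, size=s)
    for (i, j), b in bt.items():
        a, b_lab = partition.labels[i], partition.labels[j]
        if a == b_lab:
            continue
        a, b_lab = min(a, b_lab), max(a, b_lab)
        if g.has_edge(a, b_lab):
            g[a][b_lab]["weight"] += b
        else:
            g.add_edge(a, b_lab, weight=b)
    return CommunityGraph(g)


# ---------------------------------------------------------------------------
# end-to-end analysis and convergence

def analyze_ensemble(
    ensemble: TrajectoryEnsemble,
    nodes: NodeSet | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    threshold: float = DEFAULT_PERSISTENCE_THRESHOLD,
    weighted: bool = True,
    floor: float = CORRELATION_FLOOR,
    superpose_frames: bool = True,
    reference: int | str = "mean",
):
    """Contacts → correlations → network → communities, in one call.

    Returns ``(network, partition, correlation, persistence)``.
    """
    if nodes is None:
        nodes = select_nodes(ensemble.topology)
    work = (
        superpose(ensemble, fit_nodes=nodes, reference=reference)
        if superpose_frames
        else ensemble
    )
    corr = correlation_matrix(work, nodes)
    pers = contact_persistence(work, nodes, cutoff=cutoff)
    edges = contact_edges(pers, threshold=threshold)
    net = build_network(edges, corr, floor=floor)
    part = girvan_newman(net, weighted=weighted)
    return net, part, corr, pers


@dataclass
class ConvergenceReport:
    """First- vs second-half agreement of the community pipeline."""

    ari: float
    q_first: float
    q_second: float
    n_communities_first: int
    n_communities_second: int

    def to_dict(self) -> dict:
        return {
            "ari": self.ari,
            "q_first": self.q_first,
            "q_second": self.q_second,
            "n_communities_first": self.n_communities_first,
            "n_communities_second": self.n_communities_second,
        }


def half_trajectory_convergence(
    ensemble: TrajectoryEnsemble,
    **pipeline_kwargs,
) -> ConvergenceReport:
    """Run the full pipeline independently on each half of the frames and
    report the adjusted Rand index between the two partitions."""
    F = ensemble.n_frames
    if F < 4:
        raise ValueError("need at least 4 frames to compare halves")
    halves = [
        ensemble.subset_frames(slice(0, F // 2)),
        ensemble.subset_frames(slice(F // 2, F)),
    ]
    parts = []
    for half in halves:
        _, part, _, _ = analyze_ensemble(half, **pipeline_kwargs)
        parts.append(part)
    n = len(parts[0].labels)
    ari = float(
        adjusted_rand_score(
            parts[0].labels_array(n), parts[1].labels_array(n)
        )
    )
    return ConvergenceReport(
        ari,
        parts[0].q,
        parts[1].q,
        parts[0].n_communities,
        parts[1].n_communities,
    )
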