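"""Mesoscale analysis of Mapper graphs.

Labels each node by the paradigm dominating its member time points, then
computes the mesoscale invariants used to compare paradigms: four
normalized centralities (degree, eigenvector, betweenness, closeness)
averaged per dominance label, a greedy modularity-maximizing community
partition, and Newman's modularity

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j)

evaluated directly from the partition. Disconnected graphs are restricted
to their largest connected component by default (the original analysis
chose parameters so the graphs come out connected); a strict mode raises
instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import DataError, UsageError
from .mapper import MapperGraph

logger = logging.getLogger(__name__)

CENTRALITY_MEASURES = ("degree", "eigenvector", "betweenness", "closeness")

#: Dominance label of a node whose members split exactly evenly.
TIE = "TIE"


@dataclass
class NodeDominance:
    """Per-node majority paradigm label and majority fraction."""

    labels: dict[int, str]
    fractions: dict[int, float]

    def nodes_with(self, paradigm: str) -> list[int]:
        return [n for n, lab in self.labels.items() if lab == paradigm]


@dataclass
class CentralitySummary:
    """Per-paradigm mean node centrality for one subject and measure.

    ``means[p]`` is the arithmetic mean of the centrality scores over the
    nodes dominated by paradigm ``p``; TIE nodes are excluded from every
    mean. A paradigm with no dominated (scored) nodes gets ``nan`` and is
    listed in ``undefined``.
    """

    subject_id: str
    measure: str
    means: dict[str, float]
    counts: dict[str, int]
    undefined: list[str] = field(default_factory=list)


@dataclass
class ModularityResult:
    partition: dict[int, int]
    q: float


def label_nodes(graph: MapperGraph, paradigm_labels) -> NodeDominance:
    """Assign each node the strict-majority paradigm of its members.

    ``paradigm_labels`` holds one label per time index. An exact tie gets
    the sentinel :data:`TIE` with fraction 0.5.
    """
    labels = np.asarray(paradigm_labels, dtype=object)
    out_labels: dict[int, str] = {}
    out_frac: dict[int, float] = {}
    for node in graph.nodes:
        if node.members.max(initial=-1) >= len(labels):
            raise DataError(f"node {node.node_id} has a member index without a label")
        member_labels = labels[node.members]
        values, counts = np.unique(member_labels.astype(str), return_counts=True)
        top = counts.max()
        winners = values[counts == top]
        if len(winners) > 1:
            out_labels[node.node_id] = TIE
            out_frac[node.node_id] = top / node.size
        else:
            out_labels[node.node_id] = str(winners[0])
            out_frac[node.node_id] = top / node.size
    return NodeDominance(labels=out_labels, fractions=out_frac)


def _working_subgraph(graph: MapperGraph, on_disconnected: str) -> nx.Graph:
    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise DataError("empty graph")
    if nx.is_connected(g):
        return g
    if on_disconnected == "strict":
        raise DataError("graph is disconnected (strict mode)")
    largest = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    logger.warning(
        "graph is disconnected: restricting analysis to the largest "
        "connected component (%d of %d nodes)", len(largest), g.number_of_nodes()
    )
    return g.subgraph(largest).copy()


def centrality(
    graph: MapperGraph,
    measure: str,
    on_disconnected: str = "largest_cc",
) -> dict[int, float]:
    """Normalized node centrality scores.

    degree: deg/(n-1); eigenvector: principal-eigenvector entries rescaled
    to unit maximum; betweenness: pair-normalized shortest-path
    betweenness; closeness: (n-1)/sum of distances. On a disconnected
    graph, scores are computed (and returned) for the largest connected
    component only, unless ``on_disconnected="strict"``.
    """
    if measure not in CENTRALITY_MEASURES:
        raise UsageError(f"unknown centrality measure {measure!r}")
    g = _working_subgraph(graph, on_disconnected)
    if g.number_of_nodes() == 1:
        return {n: 0.0 for n in g.nodes}
    if measure == "degree":
        scores = nx.degree_centrality(g)
    elif measure == "betweenness":
        scores = nx.betweenness_centrality(g, normalized=True)
    elif measure == "closeness":
        scores = nx.closeness_centrality(g)
    else:
        # power iteration on the adjacency matrix, then unit-max rescale
        scores = nx.eigenvector_centrality(g, max_iter=1000, tol=1e-10)
        peak = max(scores.values())
        scores = {n: v / peak for n, v in scores.items()}
    return {int(n): float(v) for n, v in scores.items()}


def paradigm_mean_centrality(
    scores: dict[int, float],
    dominance: NodeDominance,
    subject_id: str = "",
    measure: str = "",
) -> CentralitySummary:
    """Average centrality per dominance label, TIE nodes excluded.

    Only nodes present in ``scores`` contribute (on a disconnected graph
    that is the largest component). A paradigm left with zero scored nodes
    gets a nan mean and is flagged in ``undefined``.
    """
    paradigms = sorted({lab for lab in dominance.labels.values() if lab != TIE})
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    undefined: list[str] = []
    for p in paradigms:
        vals = [scores[n] for n in dominance.nodes_with(p) if n in scores]
        counts[p] = len(vals)
        if vals:
            means[p] = float(np.mean(vals))
        else:
            means[p] = float("nan")
            undefined.append(p)
            logger.warning("paradigm %r dominates no scored node: mean undefined", p)
    counts[TIE] = len(dominance.nodes_with(TIE))
    return CentralitySummary(
        subject_id=subject_id, measure=measure, means=means, counts=counts, undefined=undefined
    )


def detect_communities(graph: MapperGraph, seed: int = 0) -> dict[int, int]:
    """Greedy (agglomerative) modularity-maximizing partition.

    Deterministic: the CNM greedy optimizer is used and the resulting
    communities are numbered by their smallest node id (lexicographic
    tie-break). An edgeless graph yields singleton communities. The seed
    argument is accepted for interface stability; the optimizer itself is
    deterministic.
    """
    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise DataError("empty graph")
    if g.number_of_edges() == 0:
        logger.warning("edgeless graph: every node is its own community")
        return {int(n): i for i, n in enumerate(sorted(g.nodes))}
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    return {int(n): i for i, comm in enumerate(communities) for n in comm}


def modularity(graph: MapperGraph, partition: dict[int, int]) -> float:
    """Newman modularity Q of a partition.

    Computed in the aggregated per-community form
    ``Q = sum_c (L_c/m - (d_c/2m)^2)`` with L_c the intra-community edge
    count and d_c the community degree sum, which equals the pairwise
    double sum over the adjacency matrix. Q = 0 by convention for an
    edgeless graph.
    """
    g = graph.to_networkx()
    missing = set(g.nodes) - set(partition)
    if missing:
        raise UsageError(f"partition is missing nodes: {sorted(missing)[:5]}")
    m = g.number_of_edges()
    if m == 0:
        logger.warning("edgeless graph: modularity defined as 0")
        return 0.0
    intra: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for n in g.nodes:
        degsum[partition[n]] = degsum.get(partition[n], 0) + g.degree[n]
    for u, v in g.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    q = 0.0
    for c, d in degsum.items():
        q += intra.get(c, 0) / m - (d / (2 * m)) ** 2
    return float(q)


def community_structure(graph: MapperGraph, seed: int = 0) -> ModularityResult:
    """Detect communities and score the partition with Newman's Q."""
    partition = detect_communities(graph, seed=seed)
    g = graph.to_networkx()
    if g.number_of_edges() == 0:
        return ModularityResult(partition=partition, q=0.0)
    return ModularityResult(partition=partition, q=modularity(graph, partition))
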