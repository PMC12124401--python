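"""Projection of significant links into the multimorbidity network.

Nodes are disease communities; an edge joins two communities whose shared
user count survived the degree-preserving significance filter, weighted by
the observed overlap W_ij. Node importance is strength centrality
(weighted degree) and structure is summarized by Louvain modularity
maximization on the weighted undirected graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .nullmodel import SignificantLinkTable

#: Seeded Louvain restarts; the best-modularity partition is kept. The
#: heuristic is cheap at these sizes and restarts make the optimum on
#: small graphs essentially certain while staying deterministic per seed.
N_LOUVAIN_RESTARTS = 10


@dataclass
class MultimorbidityNetwork:
    """Weighted undirected network of significantly co-engaged communities."""

    graph: nx.Graph
    partition: Optional[dict] = None

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def strength(self) -> dict:
        return {n: float(d) for n, d in self.graph.degree(weight="weight")}

    def edge_weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]


def project_network(links: SignificantLinkTable) -> MultimorbidityNetwork:
    """Build the network from retained links only.

    Edge weight is the observed overlap W_ij (not the excess over the null);
    communities incident to no retained link do not appear. Zero retained
    links is fatal — there is nothing to project.
    """
    graph = nx.Graph()
    for (a, b) in links.retained_pairs():
        rec = links.links[(a, b)]
        graph.add_edge(a, b, weight=float(rec.observed), expected_weight=float(rec.expected))
    if graph.number_of_edges() == 0:
        raise ValueError(
            "no retained links to project; relax min_users or check the input cohort"
        )
    return MultimorbidityNetwork(graph=graph)


def strength_centrality(network: MultimorbidityNetwork) -> dict:
    """Weighted degree of every node (the sum of incident edge weights)."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    return network.strength


def modularity(network: MultimorbidityNetwork, partition: dict) -> float:
    """Standard weighted undirected modularity at resolution 1."""
    blocks: dict = {}
    for node, label in partition.items():
        blocks.setdefault(label, set()).add(node)
    return nx.community.modularity(network.graph, blocks.values(), weight="weight")


def _canonical_labels(blocks, nodes) -> dict:
    """Contiguous integer labels, blocks ordered by their smallest node token."""
    ordered = sorted((min(b) for b in blocks))
    rank = {token: i for i, token in enumerate(ordered)}
    labels = {}
    for block in blocks:
        lab = rank[min(block)]
        for node in block:
            labels[node] = lab
    return {n: labels[n] for n in nodes}


def detect_communities(network: MultimorbidityNetwork, seed: int) -> dict:
    """Louvain partition of the weighted network, deterministic under seed.

    Runs several seeded restarts of networkx's Louvain implementation and
    keeps the partition of highest modularity (first found on ties). The
    partition is stored on the network and returned as a node -> contiguous
    integer label mapping.
    """
    graph = network.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    restart_seeds = np.random.SeedSequence(int(seed) & 0x7FFFFFFF).generate_state(
        N_LOUVAIN_RESTARTS
    )
    best_blocks, best_q = None, -np.inf
    for s in restart_seeds:
        blocks = nx.community.louvain_communities(graph, weight="weight", seed=int(s % 2**31))
        q = nx.community.modularity(graph, blocks, weight="weight")
        if q > best_q + 1e-15:
            best_blocks, best_q = blocks, q
    partition = _canonical_labels(best_blocks, sorted(graph.nodes))
    network.partition = partition
    return partition
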