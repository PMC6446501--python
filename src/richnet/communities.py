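"""Topological taxonomy of the gene-set graph.

The graph is decomposed in three ordered stages:

1. **singletons** — degree-0 nodes, set aside first;
2. **binary clusters** — connected components of exactly two sets;
3. **communities** — divisive Girvan–Newman clustering of what remains:
   repeatedly remove the edge of maximal edge betweenness (recomputing
   betweenness after every removal), record the component structure each
   time it changes, and keep the recorded partition that maximises
   Newman–Girvan modularity Q of the original graph.

Crossing edges of the chosen partition are then deleted, components of
size < 3 are discarded ("filtered"), and surviving communities are numbered
in decreasing size order. Edge weights are ignored throughout: community
structure here is purely topological.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "ClusterPartition",
    "find_singletons",
    "find_binary_clusters",
    "girvan_newman",
    "girvan_newman_dendrogram",
    "split_and_filter",
    "categorize",
    "partition_graph",
    "DEFAULT_MIN_CLUSTER_SIZE",
]

DEFAULT_MIN_CLUSTER_SIZE = 3

SINGLETON = "singleton"
BINARY = "binary"
COMMUNITY = "community"


@dataclass
class ClusterPartition:
    """Node-to-cluster assignment with per-cluster bookkeeping.

    ``membership`` maps each clustered node to a positive integer cluster
    id; ``category`` labels each cluster as singleton, binary or community;
    ``filtered`` lists nodes discarded by the community size filter (they
    carry no cluster id). ``modularity`` is the Q of the chosen community
    partition on the singleton- and binary-free graph (None when that graph
    is empty).
    """

    membership: dict[str, int] = field(default_factory=dict)
    category: dict[int, str] = field(default_factory=dict)
    filtered: list[str] = field(default_factory=list)
    modularity: float | None = None

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for cid in self.membership.values():
            out[cid] = out.get(cid, 0) + 1
        return out

    def clusters(self, category: str | None = None) -> dict[int, list[str]]:
        """Cluster id -> member nodes (insertion order), optionally by category."""
        out: dict[int, list[str]] = {}
        for node, cid in self.membership.items():
            if category is not None and self.category.get(cid) != category:
                continue
            out.setdefault(cid, []).append(node)
        return out


def find_singletons(g: nx.Graph) -> list[str]:
    """Nodes with no neighbours, in node order."""
    return [n for n in g.nodes if g.degree(n) == 0]


def find_binary_clusters(g: nx.Graph) -> list[tuple[str, str]]:
    """Connected components of exactly two nodes, as sorted pairs.

    Expects singletons to have been removed already; on a singleton-free
    graph these are precisely the components of size < 3. Pairs are
    returned in order of their smaller member for determinism.
    """
    pairs = [
        tuple(sorted(comp)) for comp in nx.connected_components(g) if len(comp) == 2
    ]
    return sorted(pairs)


def _max_betweenness_edge(g: nx.Graph) -> tuple[str, str]:
    """Edge of maximal betweenness; ties broken by smallest sorted (u, v)."""
    eb = nx.edge_betweenness_centrality(g, normalized=False, weight=None)
    best_edge = None
    best_val = -1.0
    for (u, v), val in eb.items():
        key = tuple(sorted((u, v)))
        if val > best_val + 1e-12 or (
            abs(val - best_val) <= 1e-12 and (best_edge is None or key < best_edge)
        ):
            best_val = val
            best_edge = key
    assert best_edge is not None
    return best_edge


def _components_partition(g: nx.Graph) -> list[frozenset[str]]:
    return [frozenset(c) for c in nx.connected_components(g)]


def girvan_newman_dendrogram(g: nx.Graph) -> list[list[frozenset[str]]]:
    """All distinct component structures along the divisive edge removal.

    The first entry is the initial component structure; each subsequent
    entry is recorded when an edge removal increases the component count,
    down to the edgeless graph. Deterministic (lexicographic tie-break).
    """
    work = nx.Graph()
    work.add_nodes_from(g.nodes)
    work.add_edges_from(g.edges)
    partitions = [_components_partition(work)]
    while work.number_of_edges() > 0:
        u, v = _max_betweenness_edge(work)
        work.remove_edge(u, v)
        parts = _components_partition(work)
        if len(parts) > len(partitions[-1]):
            partitions.append(parts)
    return partitions


def girvan_newman(g: nx.Graph) -> tuple[dict[str, int], float | None]:
    """Divisive edge-betweenness clustering with modularity cut selection.

    Builds the full dendrogram by iterated removal of the maximum-edge-
    betweenness edge (complete recomputation after each removal; on
    disconnected graphs components are handled independently and never
    merge). Among all recorded component structures — from the initial one
    down to the edgeless graph — the one maximising modularity Q of the
    *original* graph is returned; ties prefer fewer clusters. Deterministic:
    betweenness ties are resolved by the lexicographically smallest edge.

    Returns ``(membership, Q)`` where membership maps node -> community id
    (communities numbered 1.. in decreasing size order, ties by smallest
    member name). ``Q`` is None for a graph with no edges (each node then
    forms its own community).
    """
    if g.number_of_nodes() == 0:
        return {}, None
    if g.number_of_edges() == 0:
        return {n: i + 1 for i, n in enumerate(g.nodes)}, None

    partitions = girvan_newman_dendrogram(g)
    best = max(
        range(len(partitions)),
        key=lambda i: (nx.community.modularity(g, partitions[i]), -i),
    )
    chosen = partitions[best]
    q = nx.community.modularity(g, chosen)

    ordered = sorted(chosen, key=lambda c: (-len(c), min(c)))
    membership = {n: cid for cid, comm in enumerate(ordered, start=1) for n in sorted(comm)}
    return membership, q


def split_and_filter(
    g: nx.Graph,
    membership: dict[str, int],
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> tuple[nx.Graph, dict[str, int], list[str]]:
    """Delete community-crossing edges, then drop small components.

    Every edge whose endpoints lie in different communities of
    ``membership`` is removed; connected components are recomputed; nodes
    in components smaller than ``min_size`` are deleted. Surviving
    components are renumbered 1.. in decreasing size order.

    Returns ``(graph, component_membership, filtered_nodes)``.
    """
    h = nx.Graph()
    h.add_nodes_from(g.nodes(data=True))
    for u, v, d in g.edges(data=True):
        if membership[u] == membership[v]:
            h.add_edge(u, v, **d)

    comps = sorted(nx.connected_components(h), key=lambda c: (-len(c), min(c)))
    filtered = sorted(n for c in comps if len(c) < min_size for n in c)
    h.remove_nodes_from(filtered)
    new_membership = {
        n: cid
        for cid, comp in enumerate((c for c in comps if len(c) >= min_size), start=1)
        for n in sorted(comp)
    }
    return h, new_membership, filtered


def categorize(
    g: nx.Graph,
    singletons: list[str],
    binary_pairs: list[tuple[str, str]],
    community_membership: dict[str, int],
    filtered: list[str],
    modularity: float | None,
) -> ClusterPartition:
    """Merge the three stage outputs into one partition over all nodes.

    Community clusters keep their ids 1..C (already ordered by decreasing
    size); binary pairs and singletons are numbered after them. Filtered
    nodes are reported but carry no cluster id. Every original node appears
    exactly once across the four groups.
    """
    part = ClusterPartition(modularity=modularity, filtered=list(filtered))
    for node, cid in community_membership.items():
        part.membership[node] = cid
        part.category[cid] = COMMUNITY
    next_id = max(part.category, default=0) + 1
    for a, b in binary_pairs:
        part.membership[a] = next_id
        part.membership[b] = next_id
        part.category[next_id] = BINARY
        next_id += 1
    for node in singletons:
        part.membership[node] = next_id
        part.category[next_id] = SINGLETON
        next_id += 1

    accounted = set(part.membership) | set(part.filtered)
    if accounted != set(g.nodes) or len(part.membership) + len(part.filtered) != len(
        g.nodes
    ):
        raise ValueError("stage outputs do not partition the graph nodes")
    return part


def partition_graph(
    g: nx.Graph, min_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> tuple[ClusterPartition, nx.Graph]:
    """Run the full cascade: singletons -> binary clusters -> communities.

    Returns the unified partition over all nodes of ``g`` and the final
    community graph (crossing edges removed, small components dropped).
    """
    singletons = find_singletons(g)
    g1 = g.subgraph(n for n in g.nodes if n not in set(singletons)).copy()

    binary_pairs = find_binary_clusters(g1)
    in_binary = {n for pair in binary_pairs for n in pair}
    g2 = g1.subgraph(n for n in g1.nodes if n not in in_binary).copy()

    gn_membership, q = girvan_newman(g2)
    g3, comm_membership, filtered = split_and_filter(g2, gn_membership, min_size)

    part = categorize(g, singletons, binary_pairs, comm_membership, filtered, q)
    return part, g3
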