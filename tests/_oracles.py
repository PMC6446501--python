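"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive and self-contained (plain dicts and
loops, no calls into richnet and no graph library for the path counting),
so that agreement with the package implementations is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def naive_overlap(sets: list[frozenset[str]]):
    """Per-pair set-intersection loop: (counts, union, jaccard) matrices."""
    n = len(sets)
    counts = np.zeros((n, n), dtype=int)
    union = np.zeros((n, n), dtype=int)
    jacc = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                union[i, j] = len(sets[i])
                continue
            inter = len(sets[i] & sets[j])
            uni = len(sets[i] | sets[j])
            counts[i, j] = inter
            union[i, j] = uni
            jacc[i, j] = inter / uni if uni else 0.0
    return counts, union, jacc


def naive_bh(pvals) -> np.ndarray:
    """O(n^2) Benjamini-Hochberg step-up: adj_i = min over p_j >= p_i of
    n * p_j / rank(p_j), clamped to 1, with ranks counting ties."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    adj = np.empty(n)
    for i in range(n):
        candidates = []
        for j in range(n):
            if p[j] >= p[i]:
                rank_j = int((p <= p[j]).sum())
                candidates.append(n * p[j] / rank_j)
        adj[i] = min(1.0, min(candidates))
    return adj


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Enumerate all shortest s-t paths by BFS distances + DFS backtracking."""
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_edge_betweenness(nodes, edges) -> dict[tuple, float]:
    """Edge betweenness by explicit shortest-path enumeration.

    Each unordered node pair contributes 1/(number of shortest paths) to
    every edge on each of its shortest paths.
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    eb = {tuple(sorted((u, v))): 0.0 for u, v in edges}
    nodelist = sorted(nodes)
    for i, s in enumerate(nodelist):
        for t in nodelist[i + 1 :]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for a, b in zip(path, path[1:]):
                    eb[tuple(sorted((a, b)))] += w
    return eb


def brute_modularity(nodes, edges, communities) -> float:
    """Newman-Girvan Q = sum_c (e_c/m - (d_c/2m)^2) from first principles."""
    m = len(edges)
    if m == 0:
        return 0.0
    deg = {n: 0 for n in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    q = 0.0
    for comm in communities:
        within = sum(1 for u, v in edges if u in comm and v in comm)
        d_c = sum(deg[n] for n in comm)
        q += within / m - (d_c / (2.0 * m)) ** 2
    return q


def random_library(rng: np.random.Generator, n_sets=8, n_genes=40, p_member=0.3):
    """Random binary-membership library as a name->frozenset dict."""
    genes = [f"g{i}" for i in range(n_genes)]
    sets = {}
    for k in range(n_sets):
        mask = rng.random(n_genes) < p_member
        members = [g for g, keep in zip(genes, mask) if keep]
        if not members:
            members = [genes[int(rng.integers(n_genes))]]
        sets[f"S{k}"] = frozenset(members)
    return sets
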