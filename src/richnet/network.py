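"""Overlap/Jaccard matrices and construction of the gene-set graph.

Nodes are significant gene sets; two sets are joined by an edge when their
Jaccard index J = |A ∩ B| / |A ∪ B| strictly exceeds a threshold (default
0.2). Edge weights carry the shared-gene count; they are kept for export
and display but deliberately ignored by community detection.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .geneset_io import GeneSetLibrary

__all__ = [
    "OverlapMatrices",
    "overlap_matrices",
    "build_graph",
    "write_graphml",
    "write_edge_list",
    "DEFAULT_JACCARD_THRESHOLD",
]

DEFAULT_JACCARD_THRESHOLD = 0.2


@dataclass(frozen=True)
class OverlapMatrices:
    """Pairwise overlap structure over an ordered list of gene sets.

    ``counts[i, j]`` is the shared-gene count |S_i ∩ S_j| with the diagonal
    forced to zero, ``union`` the union size from the identity
    |A| + |B| - |A ∩ B|, and ``jaccard`` their ratio.
    """

    names: tuple[str, ...]
    counts: np.ndarray
    union: np.ndarray
    jaccard: np.ndarray


def overlap_matrices(
    lib: GeneSetLibrary,
    keep: Sequence[str] | None = None,
    view: str = "full",
) -> OverlapMatrices:
    """Compute shared-gene, union and Jaccard matrices over ``keep``.

    ``keep`` (default: all library names) selects and orders the sets; it
    must be a subset of the library. ``view`` selects which membership view
    similarity is based on — ``"full"`` (default) uses every curated member,
    ``"restricted"`` only genes present in the data.
    """
    names = list(lib.names) if keep is None else list(keep)
    missing = [n for n in names if n not in lib]
    if missing:
        raise KeyError(f"unknown set name(s): {missing}")
    if not names:
        raise ValueError("need at least one gene set")

    member_sets = [lib.members(n, view) for n in names]
    gene_index = {g: i for i, g in enumerate(sorted(set().union(*member_sets)))}
    M = np.zeros((len(names), max(len(gene_index), 1)), dtype=np.int64)
    for i, members in enumerate(member_sets):
        for g in members:
            M[i, gene_index[g]] = 1

    counts = M @ M.T
    sizes = counts.diagonal().copy()
    np.fill_diagonal(counts, 0)
    union = sizes[:, None] + sizes[None, :] - counts
    with np.errstate(divide="ignore", invalid="ignore"):
        jaccard = np.where(union > 0, counts / np.maximum(union, 1), 0.0)
    return OverlapMatrices(tuple(names), counts, union, jaccard)


def build_graph(
    om: OverlapMatrices,
    table: pd.DataFrame,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> nx.Graph:
    """Thresholded gene-set graph from overlap matrices and a result table.

    ``table`` must contain one row per matrix name (columns name, NGenes,
    Direction; FDR carried along when present). An edge (i, j) exists iff
    ``jaccard[i, j] > threshold`` (strictly), weighted by the shared-gene
    count. Every set becomes a node, including isolated ones.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    tab = table.set_index("name")
    missing = [n for n in om.names if n not in tab.index]
    if missing:
        raise ValueError(f"result table misaligned with matrices; missing: {missing}")

    g = nx.Graph(jaccard_threshold=float(threshold))
    for name in om.names:
        row = tab.loc[name]
        attrs = {"size": int(row["NGenes"]), "direction": str(row["Direction"])}
        if "FDR" in tab.columns and pd.notna(row.get("FDR")):
            attrs["fdr"] = float(row["FDR"])
        g.add_node(name, **attrs)
    n = len(om.names)
    for i in range(n):
        for j in range(i + 1, n):
            if om.jaccard[i, j] > threshold:
                g.add_edge(
                    om.names[i],
                    om.names[j],
                    weight=int(om.counts[i, j]),
                    shared_genes=int(om.counts[i, j]),
                    jaccard=float(om.jaccard[i, j]),
                )
    return g


def write_graphml(g: nx.Graph, path: str) -> None:
    """Export the graph as GraphML (attributes survive as typed keys)."""
    nx.write_graphml(g, path)


def write_edge_list(g: nx.Graph, path: str) -> None:
    """Export edges as TSV: source, target, jaccard, shared_genes."""
    rows = [
        (u, v, d.get("jaccard", float("nan")), d.get("shared_genes", d.get("weight")))
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "jaccard", "shared_genes"]).to_csv(
        path, sep="\t", index=False
    )
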