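"""Static network figures: whole-network views and the annotated cluster lattice.

Layouts are force-directed (Fruchterman-Reingold) with an explicit seed and
fixed iteration count so figures are reproducible; node coordinates are
always exported as a TSV sidecar next to the image so tests and downstream
consumers never need to compare pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .communities import ClusterPartition
from .labeling import ClusterLabel, format_title, node_display_label

__all__ = ["PlotStyle", "plot_network", "plot_cluster_lattice"]

#: Up/Down/Mixed palette (colorbrewer Set1 red, blue, grey)
DIRECTION_PALETTE = {"Up": "#E41A1C", "Down": "#377EB8", "Mixed": "#999999"}
EDGE_COLOR = "#99CC33"


@dataclass(frozen=True)
class PlotStyle:
    """Display parameters shared by all figures."""

    direction_palette: dict[str, str] = field(
        default_factory=lambda: dict(DIRECTION_PALETTE)
    )
    edge_color: str = EDGE_COLOR
    node_size_cap: float = 4.0  # display cap in units of sqrt(NGenes)/scale
    layout_seed: int = 7042016

    def __post_init__(self) -> None:
        if set(self.direction_palette) != {"Up", "Down", "Mixed"}:
            raise ValueError("palette must cover exactly Up, Down, Mixed")


def _node_sizes(g: nx.Graph, style: PlotStyle, scale: float = 12.0) -> list[float]:
    # area proportional to NGenes up to the display cap
    sizes = []
    for _, d in g.nodes(data=True):
        r = math.sqrt(max(int(d.get("size", 1)), 1)) / 2.0
        sizes.append(min(r, style.node_size_cap) * scale)
    return sizes


def _layout(g: nx.Graph, style: PlotStyle) -> dict[str, tuple[float, float]]:
    if g.number_of_nodes() == 0:
        return {}
    return nx.spring_layout(g, seed=style.layout_seed, iterations=50, weight=None)


def _write_coords(
    pos: dict[str, tuple[float, float]],
    path: Path,
    membership: dict[str, int] | None = None,
) -> None:
    rows = [
        (n, float(x), float(y), (membership or {}).get(n, ""))
        for n, (x, y) in pos.items()
    ]
    pd.DataFrame(rows, columns=["name", "x", "y", "cluster_id"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def _coord_sidecar(path: Path) -> Path:
    return path.with_suffix(".coords.tsv")


def plot_network(
    g: nx.Graph,
    path: str,
    style: PlotStyle | None = None,
    membership: dict[str, int] | None = None,
    title: str | None = None,
) -> Path:
    """Draw the gene-set graph colored by direction; write image + coords.

    Image format follows the file extension (png or svg). Returns the image
    path; node coordinates go to ``<stem>.coords.tsv`` alongside it.
    """
    style = style or PlotStyle()
    out = Path(path)
    pos = _layout(g, style)

    fig, ax = plt.subplots(figsize=(7, 6))
    if g.number_of_nodes() > 0:
        colors = [
            style.direction_palette.get(d.get("direction", "Mixed"), "#999999")
            for _, d in g.nodes(data=True)
        ]
        nx.draw_networkx_edges(g, pos, ax=ax, edge_color=style.edge_color, width=1.0)
        nx.draw_networkx_nodes(
            g, pos, ax=ax, node_color=colors, node_size=_node_sizes(g, style),
            linewidths=0.3, edgecolors="black",
        )
        handles = [
            plt.Line2D([], [], marker="o", ls="", color=c, label=lab)
            for lab, c in style.direction_palette.items()
        ]
        ax.legend(handles=handles, loc="lower right", fontsize=7, frameon=False)
    if title:
        ax.set_title(title, fontsize=9)
    ax.set_axis_off()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _write_coords(pos, _coord_sidecar(out), membership)
    return out


def plot_cluster_lattice(
    g: nx.Graph,
    partition: ClusterPartition,
    labels: dict[int, ClusterLabel],
    path: str,
    style: PlotStyle | None = None,
    max_panels: int = 16,
    max_members_for_labels: int = 5,
) -> Path:
    """One-page lattice of community panels with machine-generated titles.

    Communities are drawn in their id order (decreasing size), at most
    ``max_panels`` of them, in a grid of ``min(4, n_communities)`` columns.
    Panels show the auto-generated title (uppercased, truncated, optional
    line break) and per-node labels only for communities of at most
    ``max_members_for_labels`` nodes.
    """
    style = style or PlotStyle()
    out = Path(path)
    communities = partition.clusters("community")
    cids = sorted(communities)[:max_panels]

    n = max(len(cids), 1)
    ncol = min(4, n)
    nrow = math.ceil(n / ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.6 * ncol, 2.4 * nrow), squeeze=False
    )
    all_pos: dict[str, tuple[float, float]] = {}
    for ax in axes.flat:
        ax.set_axis_off()
    for ax, cid in zip(axes.flat, cids):
        members = communities[cid]
        sub = g.subgraph(members)
        pos = _layout(sub, style)
        all_pos.update(pos)
        colors = [
            style.direction_palette.get(d.get("direction", "Mixed"), "#999999")
            for _, d in sub.nodes(data=True)
        ]
        nx.draw_networkx_edges(sub, pos, ax=ax, edge_color=style.edge_color, width=0.8)
        nx.draw_networkx_nodes(
            sub, pos, ax=ax, node_color=colors, node_size=_node_sizes(sub, style, 8.0),
            linewidths=0.3, edgecolors="black",
        )
        node_labels = {
            node: lab
            for node in sub.nodes
            if (lab := node_display_label(node, len(members), max_members_for_labels))
        }
        if node_labels:
            nx.draw_networkx_labels(sub, pos, labels=node_labels, ax=ax, font_size=4)
        lbl = labels.get(cid)
        ax.set_title(format_title(lbl.title) if lbl else "", fontsize=6)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _write_coords(all_pos, _coord_sidecar(out), partition.membership)
    return out
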