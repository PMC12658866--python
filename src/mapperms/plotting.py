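"""Static plots: cover graphs with colored nodes, group pie charts.

Matplotlib only; figures are returned so callers decide whether to save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .ballmapper import BallMapperGraph
from .groups import RepresentativeGroup

__all__ = ["plot_graph", "plot_group_pies"]


def plot_graph(
    graph: BallMapperGraph,
    color_attribute: str | None = None,
    ax=None,
    seed: int = 0,
):
    """Spring-layout drawing of a Ball Mapper graph.

    Node size scales with ball membership; ``color_attribute`` may name a
    scalar node attribute (colored by value) or a proportion map (colored
    by the dominant category's share).
    """
    g = graph.to_networkx()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=seed)
    sizes = [40 + 20 * g.nodes[n]["size"] for n in g.nodes]
    colors = None
    if color_attribute and color_attribute in graph.node_attributes:
        vals = graph.node_attributes[color_attribute]
        first = next(iter(vals.values()))
        if isinstance(first, dict):
            colors = [max(vals[n].values()) if vals[n] else 0.0 for n in g.nodes]
        else:
            colors = [vals[n] for n in g.nodes]
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_size=sizes, node_color=colors,
        cmap="coolwarm", with_labels=False, edge_color="0.7",
    )
    ax.set_axis_off()
    return ax


def plot_group_pies(
    groups: list[RepresentativeGroup],
    sample_category: dict[str, str],
    max_groups: int = 12,
    ax=None,
):
    """Pie-chart view of representative groups, colored by a metadata field.

    Each group is a pie whose slices show the composition of its members
    by category (e.g. country); pie area tracks group size and dashed
    lines join groups sharing samples.
    """
    groups = groups[:max_groups]
    if not groups:
        raise ValueError("no groups to plot")
    cats = sorted({sample_category[s] for g in groups for s in g.members})
    cmap = plt.get_cmap("tab10")
    colors = {c: cmap(i % 10) for i, c in enumerate(cats)}
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 8))
    n = len(groups)
    centers = [
        (np.cos(2 * np.pi * i / n), np.sin(2 * np.pi * i / n)) for i in range(n)
    ]
    for i, g in enumerate(groups):
        for j in range(i + 1, n):
            if g.members & groups[j].members:
                (x0, y0), (x1, y1) = centers[i], centers[j]
                ax.plot([x0, x1], [y0, y1], ls="--", color="0.8", zorder=0)
    for (x, y), g in zip(centers, groups):
        counts: dict[str, int] = {}
        for s in g.members:
            c = sample_category[s]
            counts[c] = counts.get(c, 0) + 1
        total = sum(counts.values())
        radius = 0.08 + 0.05 * np.sqrt(len(g.members))
        start = 0.0
        for c in sorted(counts):
            frac = counts[c] / total
            wedge = plt.matplotlib.patches.Wedge(
                (x, y), radius, 360 * start, 360 * (start + frac),
                facecolor=colors[c], edgecolor="white", zorder=2,
            )
            ax.add_patch(wedge)
            start += frac
        ax.annotate(
            f"φ={g.phi}", (x, y - radius - 0.06), ha="center", fontsize=8
        )
    handles = [
        plt.matplotlib.patches.Patch(color=colors[c], label=c) for c in cats
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=8)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.5)
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax
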