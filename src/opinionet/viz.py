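"""Deterministic layouts and standard-format graph exports.

The wave-by-wave schism is easiest to inspect visually, so projections can be
laid out with a seeded force-directed algorithm, exported to GraphML/GEXF/CSV
for external viewers, and rendered as one multi-panel figure per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import networkx as nx

from .network import ProjectionGraph

__all__ = ["LayoutResult", "layout", "export_graph", "wave_panel", "FACTION_COLOURS"]

#: node colours keyed by semantic faction label
FACTION_COLOURS = {"truster": "white", "sceptic": "gold", "unassigned": "lightgrey"}


@dataclass
class LayoutResult:
    coordinates: dict
    algorithm: str
    seed: int
    iterations: int


def layout(graph: ProjectionGraph, seed: int = 0, iterations: int = 50) -> LayoutResult:
    """Weight-attracted spring (Fruchterman-Reingold) layout, seeded.

    A single node is placed at the origin. Identical (graph, seed,
    iterations) triples give identical coordinates.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    if g.number_of_nodes() == 1:
        node = next(iter(g.nodes))
        return LayoutResult({node: (0.0, 0.0)}, "spring", seed, iterations)
    pos = nx.spring_layout(g, weight="weight", seed=seed, iterations=iterations)
    coords = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
    return LayoutResult(coords, "spring", seed, iterations)


def _decorated(graph: ProjectionGraph, lay: LayoutResult | None,
               factions: Mapping | None) -> nx.Graph:
    g = graph.graph.copy()
    if lay is not None:
        for n, (x, y) in lay.coordinates.items():
            if n in g:
                g.nodes[n]["x"], g.nodes[n]["y"] = x, y
    if factions is not None:
        labels = getattr(factions, "labels", factions)
        sem = getattr(factions, "semantic", None) or {}
        for n in g.nodes:
            if n in labels:
                g.nodes[n]["faction"] = int(labels[n])
                g.nodes[n]["semantic"] = sem.get(labels[n], "")
    return g


def export_graph(graph: ProjectionGraph, path: str | Path, fmt: str = "graphml",
                 layout_result: LayoutResult | None = None,
                 factions: Mapping | None = None) -> Path:
    """Write a projection as GraphML, GEXF or a plain edge-list CSV.

    Edges always carry weight, sign and support; nodes carry faction and
    coordinate attributes when supplied. GraphML/GEXF re-import losslessly.
    """
    path = Path(path)
    g = _decorated(graph, layout_result, factions)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "edge_csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("u,v,weight,sign,support\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u},{v},{d['weight']},{d['sign']},{d['support']}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


def read_graphml(path: str | Path, kind: str = "participant") -> ProjectionGraph:
    """Re-import a GraphML export as a ProjectionGraph."""
    return ProjectionGraph(kind, nx.read_graphml(Path(path)))


def wave_panel(graphs: Sequence[ProjectionGraph], layouts: Sequence[LayoutResult],
               out: str | Path, factions: Sequence[Mapping | None] | None = None,
               node_size: int = 30) -> Path:
    """One figure with one panel per wave, nodes coloured by faction label."""
    if len(graphs) != len(layouts):
        raise ValueError("graphs and layouts differ in length")
    if factions is None:
        factions = [None] * len(graphs)
    if len(factions) != len(graphs):
        raise ValueError("factions list length mismatch")
    fig, axes = plt.subplots(1, len(graphs), figsize=(4 * len(graphs), 4))
    if len(graphs) == 1:
        axes = [axes]
    for ax, graph, lay, fac in zip(axes, graphs, layouts, factions):
        g = graph.graph
        pos = lay.coordinates
        colours = "tab:blue"
        if fac is not None:
            labels = getattr(fac, "labels", fac)
            sem = getattr(fac, "semantic", None) or {}
            colours = [
                FACTION_COLOURS.get(sem.get(labels.get(n), "unassigned"), "lightgrey")
                for n in g.nodes
            ]
        nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.25, width=0.5)
        nx.draw_networkx_nodes(g, pos, ax=ax, node_size=node_size,
                               node_color=colours, edgecolors="black", linewidths=0.3)
        ax.set_title(graph.provenance.get("wave_id", ""))
        ax.set_axis_off()
    out = Path(out)
    fig.savefig(out, dpi=120, metadata={"Software": None} if out.suffix == ".png" else None)
    plt.close(fig)
    return out
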