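"""Bipartite person-attitude graphs and their two unipartite projections.

Likert responses are first trichotomized into stances (+1 agree / 0 neutral /
-1 disagree relative to the scale midpoint). A bipartite graph then links each
person to each item they hold a non-neutral stance on, with the stance sign on
the edge. Two projections follow:

* **participant projection** - persons linked by the *proportion of attitudes
  shared* (same stance sign among items both answered non-neutrally);
* **attitude projection** - items linked by the net number of people holding
  them with concordant (agreement, positive edge) versus discordant
  (disagreement, negative edge) signs.

Polarization observables (edge thresholding, counts of bridging edges between
factions) operate on the participant projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .survey import ResponseMatrix

__all__ = [
    "StanceMatrix",
    "BipartiteGraph",
    "ProjectionGraph",
    "binarize",
    "build_bipartite",
    "project_participants",
    "project_attitudes",
    "threshold_edges",
    "bridging_edge_count",
]


@dataclass
class StanceMatrix:
    """Trichotomized (+1 / 0 / -1 / NaN) stances, participants x items."""

    wave_id: str
    stances: pd.DataFrame  # float frame over {-1.0, 0.0, 1.0, NaN}

    def __post_init__(self) -> None:
        vals = self.stances.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise ValueError("stances must be -1, 0, +1 or missing")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.stances.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.stances.columns)

    def to_array(self) -> np.ndarray:
        return self.stances.to_numpy(dtype=float)


@dataclass
class BipartiteGraph:
    """Signed person-item graph; edges never connect nodes of the same type."""

    person_nodes: list[str]
    item_nodes: list[str]
    graph: nx.Graph

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) if u in set(self.person_nodes) else (v, u, d["sign"])
                for u, v, d in self.graph.edges(data=True)]


@dataclass
class ProjectionGraph:
    """Weighted unipartite projection with sign and support on every edge."""

    kind: str  # "participant" | "attitude"
    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("participant", "attitude"):
            raise ValueError(f"unknown projection kind {self.kind!r}")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return [(u, v, d["weight"], d["sign"], d["support"])
                for u, v, d in self.graph.edges(data=True)]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def binarize(matrix: ResponseMatrix, rule: str = "midpoint",
             cutpoints: Mapping[str, float] | None = None,
             items: Sequence[str] | None = None) -> StanceMatrix:
    """Trichotomize responses: above cut -> +1, below -> -1, at cut -> 0.

    Under the default ``midpoint`` rule the cut is each item's scale midpoint,
    so even-length scales (e.g. 1-4) can never yield a neutral stance. With
    ``rule="custom"`` a cutpoint per item is required. By default only
    attitude-block items are binarized; pass ``items`` to override.
    """
    if items is None:
        items = [s.item_id for s in matrix.items if s.block == "attitude"]
    if rule == "midpoint":
        cuts = {i: float(matrix.item(i).scale.midpoint) for i in items}
    elif rule == "custom":
        if cutpoints is None:
            raise ValueError("custom rule requires cutpoints")
        missing = [i for i in items if i not in cutpoints]
        if missing:
            raise ValueError(f"cutpoints missing for items: {missing}")
        cuts = {i: float(cutpoints[i]) for i in items}
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    values = matrix.data[list(items)]
    out = pd.DataFrame(index=values.index, columns=list(items), dtype=float)
    for i in items:
        col = values[i]
        out[i] = np.sign(col - cuts[i])
    return StanceMatrix(matrix.wave_id, out)


def build_bipartite(stance: StanceMatrix) -> BipartiteGraph:
    """One signed edge per non-zero, non-missing stance; isolates retained."""
    g = nx.Graph()
    g.add_nodes_from(stance.participant_ids, bipartite="person")
    g.add_nodes_from(stance.item_ids, bipartite="item")
    arr = stance.to_array()
    rows, cols = np.nonzero(~np.isnan(arr) & (arr != 0))
    pids, iids = stance.participant_ids, stance.item_ids
    g.add_edges_from(
        (pids[r], iids[c], {"sign": int(arr[r, c])}) for r, c in zip(rows, cols)
    )
    return BipartiteGraph(list(pids), list(iids), g)


def _signed_arrays(stance: StanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Stance array with neutral/missing zeroed, plus its non-zero mask."""
    arr = stance.to_array()
    a = np.where(np.isnan(arr), 0.0, arr)
    return a, (a != 0).astype(float)


def project_participants(stance: StanceMatrix, min_overlap: int = 5,
                         threshold: float = 0.75) -> ProjectionGraph:
    """Participant projection: weight = proportion of shared attitudes.

    For each pair, ``compared`` counts items on which both hold a non-neutral,
    non-missing stance and ``shared`` those compared items with equal sign;
    the edge (weight shared/compared, support = compared) is emitted iff
    compared >= min_overlap and weight >= threshold.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    a, nz = _signed_arrays(stance)
    compared = nz @ nz.T
    shared = (a @ a.T + compared) / 2.0
    g = nx.Graph()
    g.add_nodes_from(stance.participant_ids)
    pids = stance.participant_ids
    n = len(pids)
    iu, ju = np.triu_indices(n, k=1)
    comp = compared[iu, ju]
    sh = shared[iu, ju]
    # shared >= threshold * compared, robust to float representation of w
    keep = (comp >= min_overlap) & (sh + 1e-9 >= threshold * comp)
    for i, j, s, cnt in zip(iu[keep], ju[keep], sh[keep], comp[keep]):
        g.add_edge(pids[i], pids[j], weight=float(s / cnt), sign=1, support=int(cnt))
    return ProjectionGraph(
        "participant", g,
        provenance={"rule": "sign-agreement", "min_overlap": min_overlap,
                    "threshold": threshold, "wave_id": stance.wave_id},
    )


def project_attitudes(stance: StanceMatrix) -> ProjectionGraph:
    """Attitude projection: items linked by net concordant minus discordant people.

    For items (a, b): C = #persons with equal non-neutral signs on both,
    D = #persons with opposite signs. An edge with sign = sign(C - D),
    weight = |C - D| and support = C + D is emitted iff C != D.
    """
    a, nz = _signed_arrays(stance)
    net = a.T @ a          # C - D
    support = nz.T @ nz    # C + D
    g = nx.Graph()
    g.add_nodes_from(stance.item_ids)
    iids = stance.item_ids
    m = len(iids)
    iu, ju = np.triu_indices(m, k=1)
    keep = net[iu, ju] != 0
    for i, j in zip(iu[keep], ju[keep]):
        nv = net[i, j]
        g.add_edge(iids[i], iids[j], weight=float(abs(nv)),
                   sign=int(np.sign(nv)), support=int(support[i, j]))
    return ProjectionGraph(
        "attitude", g,
        provenance={"rule": "net-concordance", "wave_id": stance.wave_id},
    )


def threshold_edges(graph: ProjectionGraph, threshold: float) -> ProjectionGraph:
    """Retain edges with weight >= threshold; all nodes are kept."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes(data=True))
    g.add_edges_from(
        (u, v, d) for u, v, d in graph.graph.edges(data=True)
        if d["weight"] + 1e-9 >= threshold
    )
    prov = dict(graph.provenance)
    prov["edge_threshold"] = threshold
    return ProjectionGraph(graph.kind, g, prov)


def bridging_edge_count(graph: ProjectionGraph, assignment) -> int:
    """Number of edges whose endpoints carry different faction labels.

    ``assignment`` is a mapping node -> label or any object with a ``labels``
    mapping attribute (e.g. a FactionAssignment). Few bridging edges between
    two factions indicates schism.
    """
    labels = getattr(assignment, "labels", assignment)
    unlabelled = [n for n in graph.graph.nodes if n not in labels]
    if unlabelled:
        raise KeyError(f"nodes without a faction label: {unlabelled[:5]}")
    return sum(1 for u, v in graph.graph.edges if labels[u] != labels[v])
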