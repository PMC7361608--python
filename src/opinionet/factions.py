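"""Opinion-based faction detection and cross-validation.

Factions are read off the thresholded participant projection as connected
components (the minimal formalization of visually evident clusters), then
cross-validated with k-means on the raw Likert responses. Agreement between
the two partitions is quantified with a contingency chi-square and the
adjusted Rand index, and the two factions receive semantic truster/sceptic
labels from their mean stance on anchor trust items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .network import ProjectionGraph, StanceMatrix
from .stats import AssociationResult, chi_square_independence
from .survey import ResponseMatrix

__all__ = [
    "UNASSIGNED",
    "FactionAssignment",
    "PartitionAgreement",
    "connected_components",
    "kmeans_partition",
    "compare_partitions",
    "label_factions",
]

#: cluster label for participants outside the components under analysis
UNASSIGNED = -1


@dataclass
class FactionAssignment:
    """Participant -> cluster labels with provenance and semantic names."""

    labels: dict[str, int]
    method: str  # "components" | "kmeans" | "manual"
    k: int
    semantic: dict[int, str] | None = None

    def assigned_ids(self) -> list[str]:
        return [p for p, c in self.labels.items() if c != UNASSIGNED]

    def members(self, cluster: int) -> list[str]:
        return [p for p, c in self.labels.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        sem = self.semantic or {}
        return pd.DataFrame({
            "participant_id": list(self.labels),
            "cluster": list(self.labels.values()),
            "semantic": [sem.get(c, "unassigned" if c == UNASSIGNED else "")
                         for c in self.labels.values()],
        })


@dataclass
class PartitionAgreement:
    """Correspondence between two partitions of the same participants."""

    contingency: pd.DataFrame
    chi_square: AssociationResult
    ari: float


def connected_components(graph: ProjectionGraph,
                         keep_largest: int | None = None) -> FactionAssignment:
    """Label participants by connected component of the (thresholded) projection.

    Components are numbered 0, 1, ... by decreasing size, ties broken by the
    smallest contained participant id. When ``keep_largest`` is given,
    participants outside the largest that many components are marked
    :data:`UNASSIGNED`.
    """
    if graph.graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    comps = sorted(nx.connected_components(graph.graph),
                   key=lambda c: (-len(c), min(str(n) for n in c)))
    labels: dict[str, int] = {}
    for rank, comp in enumerate(comps):
        lab = rank if keep_largest is None or rank < keep_largest else UNASSIGNED
        for node in comp:
            labels[node] = lab
    k = min(len(comps), keep_largest) if keep_largest is not None else len(comps)
    return FactionAssignment(labels=labels, method="components", k=k)


def kmeans_partition(matrix: ResponseMatrix, item_ids: Sequence[str], k: int,
                     seed: int, n_restarts: int = 10,
                     standardize: bool = False) -> FactionAssignment:
    """K-means on raw Likert values (best of ``n_restarts`` by within-cluster SS).

    Only complete cases on ``item_ids`` are clustered. Clusters are renumbered
    by decreasing size so labelling is deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = matrix.data[list(item_ids)].dropna()
    if len(sub) < k:
        raise ValueError(f"only {len(sub)} complete cases for k={k}")
    X = sub.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    ids = list(sub.index)
    order = sorted(
        range(k),
        key=lambda c: (-(raw == c).sum(),
                       min((p for p, r in zip(ids, raw) if r == c), default="")),
    )
    remap = {old: new for new, old in enumerate(order)}
    return FactionAssignment(
        labels={p: remap[r] for p, r in zip(ids, raw)}, method="kmeans", k=k,
    )


def compare_partitions(a: FactionAssignment, b: FactionAssignment,
                       correction: bool = False) -> PartitionAgreement:
    """Contingency table, chi-square independence test and adjusted Rand index."""
    if set(a.labels) != set(b.labels):
        raise ValueError("partitions cover different participant sets")
    ids = sorted(a.labels)
    la = [a.labels[p] for p in ids]
    lb = [b.labels[p] for p in ids]
    contingency = pd.crosstab(pd.Series(la, name=a.method),
                              pd.Series(lb, name=b.method))
    chi = chi_square_independence(contingency.to_numpy(), correction=correction)
    return PartitionAgreement(
        contingency=contingency, chi_square=chi,
        ari=float(adjusted_rand_score(la, lb)),
    )


def label_factions(assignment: FactionAssignment, stance: StanceMatrix,
                   anchor_items: Sequence[str] = ("trust_science", "trust_scientists"),
                   ) -> FactionAssignment:
    """Name the two clusters truster/sceptic from mean stance on anchor items.

    The cluster with the higher mean anchor stance becomes the ``truster``
    cluster. An exact tie raises, demanding explicit manual labels.
    """
    clusters = sorted({c for c in assignment.labels.values() if c != UNASSIGNED})
    if len(clusters) != 2:
        raise ValueError(f"semantic labelling requires exactly 2 clusters, got {len(clusters)}")
    missing = [i for i in anchor_items if i not in stance.item_ids]
    if missing:
        raise KeyError(f"anchor items not in stance matrix: {missing}")
    means: dict[int, float] = {}
    for c in clusters:
        members = [p for p in assignment.members(c) if p in stance.stances.index]
        if not members:
            raise ValueError(f"cluster {c} has no members in the stance matrix")
        vals = stance.stances.loc[members, list(anchor_items)].to_numpy(dtype=float)
        means[c] = float(np.nanmean(vals))
    if means[clusters[0]] == means[clusters[1]]:
        raise ValueError("anchor stances tie exactly; supply manual semantic labels")
    truster = max(clusters, key=lambda c: means[c])
    sceptic = min(clusters, key=lambda c: means[c])
    return FactionAssignment(
        labels=dict(assignment.labels), method=assignment.method, k=assignment.k,
        semantic={truster: "truster", sceptic: "sceptic"},
    )
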