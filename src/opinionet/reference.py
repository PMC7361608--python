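"""Naive double-loop reference projections, kept deliberately independent of
the vectorized implementations in :mod:`opinionet.network` so the two routes
can be checked against each other on random stance matrices."""

from __future__ import annotations

import math

from .network import StanceMatrix


def project_participants_naive(stance: StanceMatrix, min_overlap: int = 5,
                               threshold: float = 0.75) -> dict[tuple[str, str], tuple[float, int]]:
    """Pair -> (weight, support) by explicit person-by-person enumeration."""
    pids = stance.participant_ids
    iids = stance.item_ids
    cells = {(p, i): stance.stances.at[p, i] for p in pids for i in iids}
    edges: dict[tuple[str, str], tuple[float, int]] = {}
    for a_idx in range(len(pids)):
        for b_idx in range(a_idx + 1, len(pids)):
            a, b = pids[a_idx], pids[b_idx]
            compared = shared = 0
            for i in iids:
                sa, sb = cells[(a, i)], cells[(b, i)]
                if sa is None or sb is None or math.isnan(sa) or math.isnan(sb):
                    continue
                if sa == 0 or sb == 0:
                    continue
                compared += 1
                if sa == sb:
                    shared += 1
            if compared >= min_overlap and compared > 0:
                w = shared / compared
                if w >= threshold or math.isclose(w, threshold):
                    edges[(a, b)] = (w, compared)
    return edges


def project_attitudes_naive(stance: StanceMatrix) -> dict[tuple[str, str], tuple[float, int, int]]:
    """Item pair -> (weight, sign, support) by explicit enumeration."""
    pids = stance.participant_ids
    iids = stance.item_ids
    edges: dict[tuple[str, str], tuple[float, int, int]] = {}
    for x in range(len(iids)):
        for y in range(x + 1, len(iids)):
            a, b = iids[x], iids[y]
            concordant = discordant = 0
            for p in pids:
                sa, sb = stance.stances.at[p, a], stance.stances.at[p, b]
                if math.isnan(sa) or math.isnan(sb) or sa == 0 or sb == 0:
                    continue
                if sa == sb:
                    concordant += 1
                else:
                    discordant += 1
            net = concordant - discordant
            if net != 0:
                edges[(a, b)] = (abs(net), 1 if net > 0 else -1, concordant + discordant)
    return edges
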