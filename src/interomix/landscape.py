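"""Deterministic community-centrality landscape and module-centre detection.

Each node receives an influence score summed over its r-neighbourhood,

    c(i) = sum over nodes j with d(i, j) <= r of (r + 1 - d(i, j)) * w(j),

where d is unweighted shortest-path distance and w(j) is either degree(j) or
1.  The self term (d = 0) is included, so an isolated node scores
(r + 1) * w(i).  Nodes then perform a steepest ascent on the landscape: the
ascent target is the neighbour with the maximal key (score, with ties won by
the lexicographically smaller identifier) when that key strictly exceeds the
node's own key, otherwise the node targets itself.  Self-targeting nodes are
the module centres; every node belongs to the centre its ascent chain
terminates in.  The key order is strict and total, so ascent chains cannot
cycle and the whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .errors import ValidationError

__all__ = [
    "LandscapeParams",
    "ModuleAssignment",
    "centrality_landscape",
    "assign_modules",
    "summarize_modules",
]


@dataclass(frozen=True)
class LandscapeParams:
    """radius: neighbourhood cut-off r >= 1; weights: 'degree' or 'unit'."""

    radius: int = 2
    weights: str = "degree"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValidationError("landscape radius must be >= 1")
        if self.weights not in ("degree", "unit"):
            raise ValidationError("weights must be 'degree' or 'unit'")


@dataclass(frozen=True)
class ModuleAssignment:
    scores: Mapping
    target: Mapping  # node -> ascent target (neighbour or self)
    centers: tuple  # sorted self-targeting nodes
    membership: Mapping  # node -> its module's centre

    def __post_init__(self) -> None:
        for c in self.centers:
            if self.target[c] != c:
                raise ValidationError(f"centre {c!r} does not target itself")
        for node, center in self.membership.items():
            if center not in self.centers:
                raise ValidationError(f"{node!r} assigned to non-centre {center!r}")


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def centrality_landscape(network, params: LandscapeParams = LandscapeParams()) -> dict:
    """Truncated-influence score c(i) for every node."""
    g = _as_graph(network)
    r = params.radius
    if params.weights == "degree":
        w = dict(g.degree())
    else:
        w = {v: 1 for v in g}
    scores = {}
    for i in g:
        dist = nx.single_source_shortest_path_length(g, i, cutoff=r)
        scores[i] = float(sum((r + 1 - d) * w[j] for j, d in dist.items()))
    return scores


def assign_modules(network, scores: Mapping) -> ModuleAssignment:
    """Steepest ascent on the landscape; returns centres and memberships."""
    g = _as_graph(network)
    missing = [v for v in g if v not in scores]
    if missing:
        raise ValidationError(f"scores missing for node(s) {missing[:5]}")

    def beats(a, b) -> bool:
        # strict total order: higher score wins, score ties go to the
        # lexicographically smaller identifier
        return scores[a] > scores[b] or (scores[a] == scores[b] and str(a) < str(b))

    target = {}
    for v in g:
        best = v
        for nb in g.adj[v]:
            if beats(nb, best):
                best = nb
        target[v] = best
    centers = tuple(sorted(v for v in g if target[v] == v))
    membership = {}
    n_nodes = g.number_of_nodes()
    for v in g:
        chain = [v]
        cur = v
        while target[cur] != cur:
            cur = target[cur]
            chain.append(cur)
            if len(chain) > n_nodes:  # impossible under a strict order
                raise ValidationError(f"ascent cycle starting at {v!r}")
        for node in chain:
            membership[node] = cur
    return ModuleAssignment(scores=dict(scores), target=target, centers=centers,
                            membership=membership)


def summarize_modules(assignment: ModuleAssignment) -> pd.DataFrame:
    """One row per centre: module size and mean member score; sizes sum to n."""
    records = []
    for center in assignment.centers:
        members = [v for v, c in assignment.membership.items() if c == center]
        mean_score = sum(assignment.scores[v] for v in members) / len(members)
        records.append({"center": center, "size": len(members), "mean_score": mean_score})
    return pd.DataFrame(records, columns=["center", "size", "mean_score"])
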