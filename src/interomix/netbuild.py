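"""Interaction-database loading and seed-based network construction.

Two constructions are used downstream:

* **induced** — only reference edges whose *both* endpoints are seed symbols
  (the known-interaction network among an experimentally derived protein set);
* **first_neighbor** — every reference edge touching a seed, pulling in the
  seeds' direct database partners (the inferred network expanded from a
  differentially expressed gene list).

Node counts are reported twice: total (seeds are retained even when they have
no reference edge) and non-isolated.  The "network of N proteins" convention
used in interactome reports corresponds to the non-isolated count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

from .errors import FormatError, ValidationError
from .identifiers import IdentifierPolicy

log = logging.getLogger(__name__)

__all__ = [
    "InteractionDB",
    "Network",
    "NetworkSummary",
    "load_interaction_db",
    "induced_subgraph",
    "first_neighbor_network",
    "network_summary",
    "restrict_to_physical",
]

_CLASSES = ("physical", "genetic", "both")
_SIF_KIND = {"pp": "physical", "gg": "genetic"}


def _merge_kind(a: str, b: str) -> str:
    if a == b:
        return a
    return "both"


@dataclass(frozen=True)
class InteractionDB:
    """Undirected reference interaction store (no self-loops, one edge per pair)."""

    graph: nx.Graph
    label: str = "interactions"

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], label: str = "interactions") -> "InteractionDB":
        """Build from (a, b, class) triples; duplicates merge, self-loops drop."""
        g = nx.Graph()
        dropped = 0
        for a, b, kind in edges:
            if kind not in _CLASSES:
                raise ValidationError(f"unknown interaction class {kind!r}")
            if a == b:
                dropped += 1
                continue
            if g.has_edge(a, b):
                g[a][b]["kind"] = _merge_kind(g[a][b]["kind"], kind)
            else:
                g.add_edge(a, b, kind=kind)
        if dropped:
            log.info("%s: dropped %d self-loop(s)", label, dropped)
        return cls(graph=g, label=label)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class Network:
    """A subnetwork derived from an :class:`InteractionDB` and a seed set."""

    graph: nx.Graph
    mode: str  # induced | first_neighbor | final
    seeds: frozenset

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph)

    @property
    def non_isolated(self) -> frozenset:
        return frozenset(n for n, d in self.graph.degree() if d > 0)

    def edge_set(self) -> frozenset:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges())


class NetworkSummary(NamedTuple):
    total_nodes: int
    non_isolated_nodes: int
    edges: int
    components: int


def load_interaction_db(path, policy: IdentifierPolicy | None = None, label: str | None = None) -> InteractionDB:
    """Load an interaction edge list from 3-column TSV (header) or SIF.

    SIF lines are ``a pp b`` / ``a gg b`` (whitespace separated); bare-node
    lines are permitted and ignored for edge purposes.
    """
    policy = policy or IdentifierPolicy()
    path = Path(path)
    edges = []
    if path.suffix.lower() == ".sif":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if not fields:
                    continue
                if len(fields) == 1:
                    continue  # isolated node declaration
                if len(fields) != 3 or fields[1] not in _SIF_KIND:
                    raise FormatError(f"{path}: line {lineno}: malformed SIF line {line.rstrip()!r}")
                a, token, b = fields
                edges.append(
                    (policy.normalize(a), policy.normalize(b), _SIF_KIND[token])
                )
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 2:
                raise FormatError(f"{path}: line 1: expected a tab-separated header")
            has_class = len(header) >= 3
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise FormatError(f"{path}: line {lineno}: expected >= 2 fields")
                kind = fields[2].strip() if has_class and len(fields) > 2 and fields[2].strip() else "physical"
                if kind not in _CLASSES:
                    raise FormatError(f"{path}: line {lineno}: unknown interaction class {kind!r}")
                edges.append((policy.normalize(fields[0]), policy.normalize(fields[1]), kind))
    return InteractionDB.from_edges(edges, label=label or path.stem)


def restrict_to_physical(db: InteractionDB) -> InteractionDB:
    """Keep only edges with physical-evidence support (classes physical/both)."""
    g = nx.Graph()
    g.add_nodes_from(db.graph)
    for u, v, d in db.graph.edges(data=True):
        if d.get("kind") in ("physical", "both"):
            g.add_edge(u, v, kind=d["kind"])
    return InteractionDB(graph=g, label=db.label + "|physical")


def induced_subgraph(db: InteractionDB, seeds: Iterable, mode: str = "induced") -> Network:
    """Network of db edges with *both* endpoints in ``seeds``.

    The node set is exactly ``seeds`` — seeds without any qualifying edge stay
    in the graph as isolated nodes and are reported separately by
    :func:`network_summary`.
    """
    seeds = frozenset(seeds)
    g = nx.Graph()
    g.add_nodes_from(seeds)
    present = seeds & set(db.graph)
    for u, v, d in db.graph.subgraph(present).edges(data=True):
        g.add_edge(u, v, kind=d.get("kind", "physical"))
    return Network(graph=g, mode=mode, seeds=seeds)


def first_neighbor_network(db: InteractionDB, seeds: Iterable) -> Network:
    """Network of db edges with *at least one* endpoint in ``seeds``.

    The node set is the seeds plus every database partner of a seed.
    """
    seeds = frozenset(seeds)
    g = nx.Graph()
    g.add_nodes_from(seeds)
    for s in seeds & set(db.graph):
        for nb, d in db.graph.adj[s].items():
            g.add_edge(s, nb, kind=d.get("kind", "physical"))
    return Network(graph=g, mode="first_neighbor", seeds=seeds)


def network_summary(network: Network) -> NetworkSummary:
    """Total/non-isolated node counts, edge count and connected components."""
    g = network.graph
    return NetworkSummary(
        total_nodes=g.number_of_nodes(),
        non_isolated_nodes=len(network.non_isolated),
        edges=g.number_of_edges(),
        components=nx.number_connected_components(g) if g.number_of_nodes() else 0,
    )
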