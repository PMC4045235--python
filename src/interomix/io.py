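"""Readers and writers for the pipeline's tabular and network formats.

Formats handled here:

* bait–prey hit tables (TSV with columns ``bait``, ``prey``, ``peptide_count``)
* GMT gene-set collections (``set_id<TAB>description<TAB>member...``)
* expression matrices (probes x samples TSV) with a two-column group file and
  a two-column probe->gene annotation file
* network export/import as edge-TSV, SIF and GraphML

All identifiers pass through an :class:`~interomix.identifiers.IdentifierPolicy`
on the way in, so downstream set operations are exact string joins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError
from .identifiers import IdentifierPolicy

log = logging.getLogger(__name__)

__all__ = [
    "HitTable",
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "read_hit_table",
    "read_gmt",
    "read_expression",
    "read_synonyms",
    "export_network",
    "import_edge_tsv",
]

EXPORT_FORMATS = ("edge-tsv", "sif", "graphml")

# SIF relation tokens: physical edges vs edges supported by both physical and
# genetic evidence (genetic-only edges also use "gg").
_SIF_TOKEN = {"physical": "pp", "genetic": "gg", "both": "gg"}


@dataclass(frozen=True)
class HitTable:
    """Bait–prey evidence from one affinity-purification MS experiment."""

    rows: pd.DataFrame  # columns: bait, prey, peptide_count
    experiment_label: str = ""

    def __post_init__(self) -> None:
        required = {"bait", "prey", "peptide_count"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"hit table missing columns {sorted(missing)}")
        if (self.rows["peptide_count"] < 1).any():
            raise ValidationError("peptide_count must be >= 1")
        if self.rows.duplicated(subset=["bait", "prey"]).any():
            raise ValidationError("duplicate (bait, prey) rows after load")

    @property
    def preys(self) -> frozenset:
        return frozenset(self.rows["prey"])

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways, complexes, ...) with a collection label."""

    sets: tuple
    label: str = ""

    def __post_init__(self) -> None:
        for gs in self.sets:
            if not gs.members:
                raise ValidationError(f"gene set {gs.set_id!r} is empty")
        ids = [gs.set_id for gs in self.sets]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate gene-set ids in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for gs in self.sets:
            if gs.set_id == set_id:
                return gs
        raise KeyError(set_id)

    def member_union(self) -> frozenset:
        out: set = set()
        for gs in self.sets:
            out |= gs.members
        return frozenset(out)


@dataclass
class ExpressionMatrix:
    """Probe-level expression with sample group labels and probe annotation.

    ``values`` holds probes in rows and samples in columns; ``scale`` declares
    whether values are linear or log2 (fold changes are always computed on the
    linear scale).  ``annotation`` maps probe id -> gene symbol and may cover
    only a subset of probes.
    """

    values: pd.DataFrame
    groups: pd.Series  # sample -> "case" | "control"
    scale: str = "linear"
    annotation: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"scale must be linear or log2, got {self.scale!r}")
        samples = list(self.values.columns)
        missing = [s for s in samples if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        bad = set(self.groups.loc[samples]) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        labels = self.groups.loc[samples]
        if (labels == "case").sum() < 1 or (labels == "control").sum() < 1:
            raise ValidationError("need at least one case and one control sample")

    def samples_in(self, group: str) -> list:
        labels = self.groups.loc[list(self.values.columns)]
        return [s for s, g in labels.items() if g == group]


def read_hit_table(
    path, policy: IdentifierPolicy | None = None, label: str | None = None
) -> HitTable:
    """Load a bait–prey TSV; duplicate (bait, prey) rows merge by max peptide count."""
    policy = policy or IdentifierPolicy()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["bait", "prey", "peptide_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    counts = []
    for i, raw in enumerate(df["peptide_count"], start=2):  # line 1 is the header
        try:
            counts.append(int(str(raw).strip()))
        except (TypeError, ValueError):
            raise FormatError(f"{path}: line {i}: non-integer peptide_count {raw!r}") from None
    df = pd.DataFrame(
        {
            "bait": [policy.normalize(b, context=f"{path} bait") for b in df["bait"]],
            "prey": [policy.normalize(p, context=f"{path} prey") for p in df["prey"]],
            "peptide_count": counts,
        }
    )
    if (df["peptide_count"] < 1).any():
        bad = df.loc[df["peptide_count"] < 1].index[0] + 2
        raise FormatError(f"{path}: line {bad}: peptide_count must be >= 1")
    n_raw = len(df)
    df = (
        df.groupby(["bait", "prey"], as_index=False, sort=True)["peptide_count"].max()
    )
    if len(df) < n_raw:
        log.info("%s: merged %d duplicate (bait, prey) rows", path, n_raw - len(df))
    log.info("%s: %d hit rows", path, len(df))
    return HitTable(rows=df, experiment_label=label or path.stem)


def read_gmt(path, policy: IdentifierPolicy | None = None, label: str | None = None) -> GeneSetCollection:
    """Load a GMT file: one gene set per line, ``id<TAB>description<TAB>members...``."""
    policy = policy or IdentifierPolicy()
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            set_id, desc, *members = fields
            norm = frozenset(
                policy.normalize(m, context=f"{path} line {lineno}")
                for m in members
                if m.strip()
            )
            if not norm:
                raise FormatError(f"{path}: line {lineno}: gene set {set_id!r} has no members")
            sets.append(GeneSet(set_id=set_id.strip(), description=desc.strip(), members=norm))
    return GeneSetCollection(sets=tuple(sets), label=label or path.stem)


def read_expression(
    matrix_path,
    groups_path,
    annotation_path=None,
    policy: IdentifierPolicy | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Load an expression matrix TSV plus group labels and optional annotation."""
    policy = policy or IdentifierPolicy()
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(groups_df.columns):
        raise FormatError(f"{groups_path}: expected columns 'sample' and 'group'")
    groups = pd.Series(groups_df["group"].values, index=groups_df["sample"].values)
    annotation: dict[str, str] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        if not {"probe", "gene"} <= set(ann.columns):
            raise FormatError(f"{annotation_path}: expected columns 'probe' and 'gene'")
        for probe, gene in zip(ann["probe"], ann["gene"]):
            if isinstance(gene, str) and gene.strip():
                annotation[str(probe).strip()] = policy.normalize(gene)
    return ExpressionMatrix(values=values, groups=groups, scale=scale, annotation=annotation)


def read_synonyms(path, policy_kwargs: Optional[dict] = None) -> IdentifierPolicy:
    """Build an :class:`IdentifierPolicy` from a two-column alias TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"alias", "canonical"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'alias' and 'canonical'")
    synonyms = dict(zip(df["alias"], df["canonical"]))
    return IdentifierPolicy(synonyms=synonyms, **(policy_kwargs or {}))


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def export_network(network, format: str, path) -> Path:
    """Write a network as edge-TSV, SIF or GraphML.

    Edge-TSV and SIF write each undirected edge once (endpoints sorted); SIF
    additionally writes isolated nodes as bare lines, the standard convention.
    GraphML (via networkx) preserves node attributes and isolated nodes.
    """
    g = _as_graph(network)
    path = Path(path)
    fmt = format.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValidationError(f"unknown export format {format!r}; expected one of {EXPORT_FORMATS}")
    edges = sorted((min(u, v), max(u, v), d.get("kind", "physical")) for u, v, d in g.edges(data=True))
    if fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tclass\n")
            for u, v, kind in edges:
                fh.write(f"{u}\t{v}\t{kind}\n")
    elif fmt == "sif":
        covered = {n for u, v, _ in edges for n in (u, v)}
        with open(path, "w") as fh:
            for u, v, kind in edges:
                fh.write(f"{u} {_SIF_TOKEN[kind]} {v}\n")
            for node in sorted(set(g) - covered):
                fh.write(f"{node}\n")
    else:
        nx.write_graphml(g, path)
    return path


def import_edge_tsv(path) -> nx.Graph:
    """Read an edge-TSV written by :func:`export_network` back into a graph."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["node_a", "node_b"]:
            raise FormatError(f"{path}: expected edge-TSV header node_a/node_b")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >= 2 fields")
            kind = fields[2] if len(fields) > 2 else "physical"
            g.add_edge(fields[0], fields[1], kind=kind)
    return g
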