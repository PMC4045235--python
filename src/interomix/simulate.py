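"""Synthetic multi-omic inputs with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a connected scale-free reference interaction graph (preferential
  attachment) containing a *planted disease module* — a connected gene subset
  with densified internal edges, standing in for the complex around the
  disease proteins;
* three bait IP/MS hit lists that all contain the module (the true
  interactors, multi-peptide), share a pool of background contaminants that
  also appear in no-antibody control pulldowns, and carry bait-specific noise
  preys, a fraction of which have single-peptide support;
* a case/control expression matrix in which the planted differentially
  expressed genes (the module plus distractors) carry a true ±fold effect
  under multiplicative log-normal noise, with several probes per gene;
* gene-set collections with one planted set whose members are
  over-represented in the module by a configurable enrichment factor.

Every generator is a pure function of (config, seed): stage-specific RNG
streams are derived from the config seed, so outputs are byte-identical
across runs and independent of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, GeneSet, GeneSetCollection, HitTable
from .netbuild import InteractionDB

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "simulate_ppi_db",
    "simulate_ipms",
    "simulate_expression",
    "simulate_genesets",
    "simulate_all",
    "write_inputs",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the emulated study design: three bait pulldowns against
    three no-antibody controls, four case versus three control expression
    samples, a true ±2.5-fold expression effect selected at a ±2 threshold
    downstream, and single-peptide/contaminant noise that makes each
    cleaning rule consequential.
    """

    n_genes: int = 2000
    attachment: int = 2  # preferential-attachment edges per new node
    module_size: int = 60
    module_edge_prob: float = 0.15  # extra internal edge density of the module
    n_baits: int = 3
    n_controls: int = 3
    peptide_mean: float = 4.0  # Poisson mean of peptide counts, floored at 2
    contaminant_pool: int = 150
    bait_contaminant_rate: float = 0.6
    control_sampling_rate: float = 0.5
    noise_preys_per_bait: int = 100
    noise_single_peptide_frac: float = 0.6
    n_case: int = 4
    n_control_samples: int = 3
    planted_fold: float = 2.5
    noise_sd: float = 0.25  # sd of the log-normal multiplicative noise
    probes_per_gene: int = 2
    n_unannotated_probes: int = 20
    n_distractor_de: int = 40
    n_gene_sets: int = 50
    set_size_range: Tuple[int, int] = (10, 40)
    enrichment_factor: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ConfigError("module_size cannot exceed n_genes")
        if self.n_genes < 1 or self.n_baits < 1:
            raise ConfigError("n_genes and n_baits must be >= 1")
        if self.planted_fold <= 1:
            raise ConfigError("planted_fold must be > 1")
        if self.set_size_range[0] < 1 or self.set_size_range[0] > self.set_size_range[1]:
            raise ConfigError("invalid set_size_range")
        if self.enrichment_factor < 0 or self.noise_sd < 0:
            raise ConfigError("rates and noise levels must be >= 0")
        if self.contaminant_pool + self.module_size > self.n_genes:
            raise ConfigError("contaminant pool and module must fit in the gene universe")


@dataclass
class SimTruth:
    """Ground truth sufficient to score every pipeline stage."""

    genes: tuple
    module_genes: frozenset
    contaminant_pool: frozenset = frozenset()
    bait_true: Mapping[str, frozenset] = field(default_factory=dict)
    bait_contaminants: Mapping[str, frozenset] = field(default_factory=dict)
    bait_noise: Mapping[str, frozenset] = field(default_factory=dict)
    de_genes: Mapping[str, float] = field(default_factory=dict)  # gene -> true fold
    planted_set_id: Optional[str] = None

    def to_json(self) -> dict:
        return {
            "module_genes": sorted(self.module_genes),
            "contaminant_pool": sorted(self.contaminant_pool),
            "bait_true": {b: sorted(s) for b, s in self.bait_true.items()},
            "bait_contaminants": {b: sorted(s) for b, s in self.bait_contaminants.items()},
            "bait_noise": {b: sorted(s) for b, s in self.bait_noise.items()},
            "de_genes": {g: self.de_genes[g] for g in sorted(self.de_genes)},
            "planted_set_id": self.planted_set_id,
        }


@dataclass
class SimData:
    """All generated inputs plus their ground truth."""

    config: SimConfig
    db: InteractionDB
    truth: SimTruth
    bait_hits: Mapping[str, HitTable]
    control_hits: Sequence[HitTable]
    expression: ExpressionMatrix
    collection: GeneSetCollection


def _rng(stage: int, config: SimConfig) -> np.random.Generator:
    # independent, order-insensitive stream per stage
    return np.random.default_rng([stage, config.rng_seed])


def _gene_names(n: int) -> list:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_ppi_db(config: SimConfig) -> tuple:
    """Scale-free reference graph with a planted, densified, connected module."""
    rng = _rng(1, config)
    genes = _gene_names(config.n_genes)
    if config.n_genes == 1:
        g = nx.Graph()
        g.add_node(genes[0])
        truth = SimTruth(genes=tuple(genes), module_genes=frozenset(genes[: config.module_size]))
        return InteractionDB(graph=g, label="synthetic"), truth
    m = min(config.attachment, config.n_genes - 1)
    raw = nx.barabasi_albert_graph(config.n_genes, m, seed=rng)
    g = nx.relabel_nodes(raw, {i: genes[i] for i in range(config.n_genes)})

    # planted module: randomized BFS ball around a random start -> connected
    start = genes[int(rng.integers(config.n_genes))]
    module: list = [start]
    chosen = {start}
    frontier = [start]
    while len(module) < config.module_size and frontier:
        nxt = []
        for node in frontier:
            nbrs = [x for x in g.adj[node] if x not in chosen]
            rng.shuffle(nbrs)
            for x in nbrs:
                if len(module) >= config.module_size:
                    break
                chosen.add(x)
                module.append(x)
                nxt.append(x)
        frontier = nxt
    if len(module) < config.module_size:  # graph smaller than the ball; top up
        rest = [x for x in genes if x not in chosen]
        extra = rng.choice(rest, size=config.module_size - len(module), replace=False)
        module.extend(str(x) for x in extra)
    module_sorted = sorted(module)

    # densify internal edges, then guarantee internal connectivity
    for i, a in enumerate(module_sorted):
        for b in module_sorted[i + 1:]:
            if not g.has_edge(a, b) and rng.random() < config.module_edge_prob:
                g.add_edge(a, b)
    induced = g.subgraph(module_sorted)
    comps = sorted(nx.connected_components(induced), key=lambda c: sorted(c)[0])
    reps = [sorted(c)[0] for c in comps]
    for a, b in zip(reps, reps[1:]):
        g.add_edge(a, b)

    kinds = rng.choice(["physical", "genetic", "both"], size=g.number_of_edges(),
                       p=[0.7, 0.2, 0.1])
    for (u, v), kind in zip(sorted(map(lambda e: tuple(sorted(e)), g.edges())), kinds):
        g[u][v]["kind"] = str(kind)
    truth = SimTruth(genes=tuple(genes), module_genes=frozenset(module_sorted))
    return InteractionDB(graph=g, label="synthetic"), truth


def _counts(rng: np.random.Generator, n: int, mean: float, floor: int) -> np.ndarray:
    return np.maximum(floor, rng.poisson(mean, size=n))


def simulate_ipms(truth: SimTruth, config: SimConfig) -> tuple:
    """Per-bait hit tables plus no-antibody control hit lists.

    Each bait recovers every module gene at >= 2 peptides, a random share of
    the shared contaminant pool, and bait-specific noise preys (a fraction at
    a single peptide).  Controls sample the contaminant pool only.
    """
    rng = _rng(2, config)
    genes = list(truth.genes)
    non_module = [x for x in genes if x not in truth.module_genes]
    pool = sorted(str(x) for x in rng.choice(non_module, size=min(config.contaminant_pool, len(non_module)), replace=False))
    truth.contaminant_pool = frozenset(pool)
    free = [x for x in non_module if x not in truth.contaminant_pool]

    bait_hits = {}
    module_sorted = sorted(truth.module_genes)
    for b in range(1, config.n_baits + 1):
        bait = f"BAIT{b}"
        true_counts = _counts(rng, len(module_sorted), config.peptide_mean, 2)
        keep = rng.random(len(pool)) < config.bait_contaminant_rate
        contams = [p for p, k in zip(pool, keep) if k]
        contam_counts = _counts(rng, len(contams), config.peptide_mean, 2)
        n_noise = min(config.noise_preys_per_bait, len(free))
        noise = sorted(str(x) for x in rng.choice(free, size=n_noise, replace=False))
        single = rng.random(n_noise) < config.noise_single_peptide_frac
        noise_counts = np.where(single, 1, _counts(rng, n_noise, config.peptide_mean, 2))
        rows = pd.DataFrame(
            {
                "bait": bait,
                "prey": module_sorted + contams + noise,
                "peptide_count": np.concatenate([true_counts, contam_counts, noise_counts]).astype(int),
            }
        )
        rows = rows.groupby(["bait", "prey"], as_index=False, sort=True)["peptide_count"].max()
        bait_hits[bait] = HitTable(rows=rows, experiment_label=bait)
        truth.bait_true = {**truth.bait_true, bait: frozenset(module_sorted)}
        truth.bait_contaminants = {**truth.bait_contaminants, bait: frozenset(contams)}
        truth.bait_noise = {**truth.bait_noise, bait: frozenset(noise)}

    controls = []
    for c in range(1, config.n_controls + 1):
        label = f"CTRL{c}"
        keep = rng.random(len(pool)) < config.control_sampling_rate
        preys = [p for p, k in zip(pool, keep) if k]
        if not preys:  # a control that catches nothing still needs a valid table
            preys = [pool[int(rng.integers(len(pool)))]] if pool else []
        counts = np.maximum(1, rng.poisson(config.peptide_mean, size=len(preys)))
        rows = pd.DataFrame({"bait": label, "prey": preys, "peptide_count": counts.astype(int)})
        rows = rows.groupby(["bait", "prey"], as_index=False, sort=True)["peptide_count"].max()
        controls.append(HitTable(rows=rows, experiment_label=label))
    return bait_hits, controls


def simulate_expression(truth: SimTruth, config: SimConfig) -> ExpressionMatrix:
    """Probe-level case/control matrix with planted ±fold genes (linear scale)."""
    rng = _rng(3, config)
    genes = list(truth.genes)
    non_module = [x for x in genes if x not in truth.module_genes]
    n_extra = min(config.n_distractor_de, len(non_module))
    distractors = sorted(str(x) for x in rng.choice(non_module, size=n_extra, replace=False))
    de_genes = sorted(set(truth.module_genes) | set(distractors))
    signs = rng.random(len(de_genes)) < 0.5
    truth.de_genes = {
        g: (config.planted_fold if up else 1.0 / config.planted_fold)
        for g, up in zip(de_genes, signs)
    }

    samples = [f"CASE{i}" for i in range(1, config.n_case + 1)] + [
        f"CTRL{i}" for i in range(1, config.n_control_samples + 1)
    ]
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control_samples, index=samples
    )
    gene_base = rng.lognormal(mean=np.log(100.0), sigma=0.8, size=len(genes))
    fold = np.array([truth.de_genes.get(g, 1.0) for g in genes])

    probe_rows = []
    annotation = {}
    values = []
    for rep in range(1, config.probes_per_gene + 1):
        probe_ids = [f"P{rep}_{i:05d}" for i in range(1, len(genes) + 1)]
        base = gene_base * rng.lognormal(mean=0.0, sigma=0.3, size=len(genes))
        noise = rng.lognormal(mean=0.0, sigma=config.noise_sd,
                              size=(len(genes), len(samples))) if config.noise_sd > 0 else np.ones((len(genes), len(samples)))
        block = base[:, None] * noise
        block[:, : config.n_case] *= fold[:, None]
        probe_rows.extend(probe_ids)
        annotation.update(dict(zip(probe_ids, genes)))
        values.append(block)
    if config.n_unannotated_probes:
        probe_ids = [f"PX_{i:05d}" for i in range(1, config.n_unannotated_probes + 1)]
        base = rng.lognormal(mean=np.log(100.0), sigma=0.8, size=len(probe_ids))
        noise = rng.lognormal(mean=0.0, sigma=max(config.noise_sd, 1e-12),
                              size=(len(probe_ids), len(samples)))
        probe_rows.extend(probe_ids)
        values.append(base[:, None] * noise)
    matrix = pd.DataFrame(np.vstack(values), index=probe_rows, columns=samples)
    return ExpressionMatrix(values=matrix, groups=groups, scale="linear", annotation=annotation)


def simulate_genesets(truth: SimTruth, config: SimConfig) -> GeneSetCollection:
    """Random gene sets with one planted set enriched in the module.

    The planted set draws a fraction ``enrichment_factor * module_size /
    n_genes`` of its members from the module (capped at 1); factor 1 makes it
    statistically indistinguishable from the random sets.
    """
    rng = _rng(4, config)
    genes = list(truth.genes)
    module_sorted = sorted(truth.module_genes)
    non_module = [x for x in genes if x not in truth.module_genes]
    lo, hi = config.set_size_range
    planted_idx = int(rng.integers(config.n_gene_sets)) if config.n_gene_sets else -1
    sets = []
    for i in range(config.n_gene_sets):
        set_id = f"S{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        if i == planted_idx:
            frac = min(1.0, config.enrichment_factor * config.module_size / config.n_genes)
            n_mod = min(len(module_sorted), int(round(frac * size)))
            members = set(str(x) for x in rng.choice(module_sorted, size=n_mod, replace=False))
            rest = rng.choice(non_module, size=min(size - n_mod, len(non_module)), replace=False)
            members |= {str(x) for x in rest}
            truth.planted_set_id = set_id
        else:
            members = {str(x) for x in rng.choice(genes, size=size, replace=False)}
        sets.append(GeneSet(set_id=set_id, description=f"synthetic set {set_id}",
                            members=frozenset(members)))
    return GeneSetCollection(sets=tuple(sets), label="synthetic")


def simulate_all(config: SimConfig = SimConfig()) -> SimData:
    """Generate every pipeline input plus ground truth for one seed."""
    db, truth = simulate_ppi_db(config)
    bait_hits, control_hits = simulate_ipms(truth, config)
    expression = simulate_expression(truth, config)
    collection = simulate_genesets(truth, config)
    return SimData(config=config, db=db, truth=truth, bait_hits=bait_hits,
                   control_hits=control_hits, expression=expression, collection=collection)


def write_inputs(data: SimData, outdir) -> dict:
    """Write all inputs as pipeline-ready text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"hit_tables": {}, "control_tables": []}
    for bait, table in data.bait_hits.items():
        p = outdir / f"hits_{bait}.tsv"
        table.rows.to_csv(p, sep="\t", index=False)
        paths["hit_tables"][bait] = str(p)
    for table in data.control_hits:
        p = outdir / f"hits_{table.experiment_label}.tsv"
        table.rows.to_csv(p, sep="\t", index=False)
        paths["control_tables"].append(str(p))

    p = outdir / "expression.tsv"
    data.expression.values.to_csv(p, sep="\t", index_label="probe")
    paths["expression"] = str(p)
    p = outdir / "groups.tsv"
    pd.DataFrame({"sample": data.expression.groups.index,
                  "group": data.expression.groups.values}).to_csv(p, sep="\t", index=False)
    paths["groups"] = str(p)
    p = outdir / "annotation.tsv"
    ann = data.expression.annotation
    pd.DataFrame({"probe": list(ann), "gene": [ann[k] for k in ann]}).to_csv(
        p, sep="\t", index=False)
    paths["annotation"] = str(p)

    p = outdir / "interactions.tsv"
    with open(p, "w") as fh:
        fh.write("node_a\tnode_b\tclass\n")
        for u, v in sorted(map(lambda e: tuple(sorted(e)), data.db.graph.edges())):
            fh.write(f"{u}\t{v}\t{data.db.graph[u][v].get('kind', 'physical')}\n")
    paths["interaction_db"] = str(p)

    p = outdir / "genesets.gmt"
    with open(p, "w") as fh:
        for gs in data.collection:
            fh.write("\t".join([gs.set_id, gs.description] + sorted(gs.members)) + "\n")
    paths["gene_sets"] = str(p)

    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(data.truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = str(p)
    return paths
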