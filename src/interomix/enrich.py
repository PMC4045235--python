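"""Hypergeometric over-representation analysis of gene-set collections.

Each gene set is scored by the upper-tail hypergeometric probability of its
overlap with the query, conditioned on a universe (default: the union of all
collection members, the convention of annotation-based enrichment services).
Unadjusted probabilities are corrected for multiple testing across the
collection with Benjamini–Hochberg by default (Bonferroni and no adjustment
are selectable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .integrate import hypergeom_upper_tail
from .io import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "map_query_to_set",
    "bh_adjust",
    "enrich_collection",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_unadjusted: float
    p_adjusted: float
    mapped: tuple  # sorted query symbols mapping to the set

    def __post_init__(self) -> None:
        if self.k != len(self.mapped):
            raise ValidationError("k must equal the number of mapped identifiers")
        if self.k > min(self.n, self.K):
            raise ValidationError("k exceeds min(n, K)")
        if self.p_adjusted + 1e-12 < self.p_unadjusted:
            raise ValidationError("adjusted p below unadjusted p")


def map_query_to_set(query: Iterable, gene_set: Iterable) -> tuple:
    """Sorted intersection of the query with one gene set's members."""
    return tuple(sorted(frozenset(query) & frozenset(gene_set)))


def bh_adjust(pvalues: Sequence[float], method: str = "bh") -> list:
    """Multiple-testing adjustment in the original input order.

    ``bh`` applies the Benjamini–Hochberg step-up (q_i = min_{j>=i} m p_(j)/j,
    capped at 1), ``bonferroni`` the Bonferroni bound, ``none`` is identity.
    Values must lie in (0, 1].
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return []
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    if method == "none":
        return [float(p) for p in ps]
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return [float(q) for q in multipletests(ps, method=key)[1]]


def enrich_collection(
    query: Iterable,
    collection: GeneSetCollection,
    universe: Iterable | None = None,
    adjust: str = "bh",
) -> list:
    """One :class:`EnrichmentRow` per gene set, sorted by p then set name.

    Gene sets and the query are clipped to the universe; when ``universe`` is
    None the union of all collection members is used.
    """
    uni = frozenset(universe) if universe is not None else collection.member_union()
    if not uni:
        raise ValidationError("empty universe")
    q_raw = frozenset(query)
    q = q_raw & uni
    if len(q) < len(q_raw):
        log.info("enrichment: %d query symbol(s) outside the universe dropped",
                 len(q_raw) - len(q))
    n, N = len(q), len(uni)
    partial = []
    for gs in collection:
        members = gs.members & uni
        mapped = map_query_to_set(q, members)
        k, K = len(mapped), len(members)
        tail = hypergeom_upper_tail(k, K, n, N)
        partial.append((gs, k, K, mapped, tail.p))
    adjusted = bh_adjust([p for *_, p in partial], method=adjust)
    rows = [
        EnrichmentRow(
            set_id=gs.set_id,
            name=gs.description or gs.set_id,
            k=k,
            K=K,
            n=n,
            N=N,
            p_unadjusted=p,
            p_adjusted=min(1.0, max(q_adj, p)),
            mapped=mapped,
        )
        for (gs, k, K, mapped, p), q_adj in zip(partial, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_unadjusted, r.name, r.set_id))
    return rows


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path) -> Path:
    """Write rows in the standard column order; mapped ids semicolon-joined."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("set\tname\tk\tK\tn\tN\tp_unadjusted\tp_adjusted\tmapped_identifiers\n")
        for r in rows:
            fh.write(
                f"{r.set_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_unadjusted:.6g}\t{r.p_adjusted:.6g}\t{';'.join(r.mapped)}\n"
            )
    return path
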