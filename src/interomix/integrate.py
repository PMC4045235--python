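"""Overlap scoring and the final disease interactome.

The proteomic (IP/MS common interactors) and transcriptomic (inferred network
nodes) layers are intersected, and the size of the intersection is scored
against the hypergeometric null: drawing n symbols uniformly without
replacement from a universe of N that contains K reference symbols,

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n).

The tail is computed in log space so that probabilities far below the
smallest positive double (observed overlaps can sit hundreds of orders of
magnitude into the tail) are still representable through their log10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Union

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .errors import ValidationError
from .netbuild import InteractionDB, Network, induced_subgraph

log = logging.getLogger(__name__)

__all__ = [
    "TailProbability",
    "OverlapTestResult",
    "hypergeom_upper_tail",
    "overlap_significance",
    "final_interactome",
]


class TailProbability(NamedTuple):
    """Upper-tail probability with a log10 companion for extreme tails."""

    p: float
    log10_p: float


@dataclass(frozen=True)
class OverlapTestResult:
    k: int
    n: int
    K: int
    N: int
    p: float
    log10_p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) <= self.N):
            raise ValidationError("inconsistent overlap counts")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError("p must lie in (0, 1]")
        if self.p == 0.0 and self.log10_p > -300.0:
            # exact p is always positive; a stored 0.0 only encodes double
            # underflow, in which case log10_p carries the value
            raise ValidationError("p may only be 0.0 under float underflow")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> TailProbability:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    Parameters follow the over-representation convention: universe size N,
    K reference successes, n draws, k observed successes.  ``k = 0`` returns
    exactly 1.  Inconsistent arguments raise :class:`ValidationError`.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)):
            raise ValidationError(f"{name} must be an integer, got {v!r}")
    if N < 1:
        raise ValidationError("universe size N must be >= 1")
    if min(k, K, n) < 0 or max(n, K) > N:
        raise ValidationError(f"inconsistent arguments k={k} K={K} n={n} N={N}")
    upper = min(n, K)
    if k > upper:
        raise ValidationError(f"k={k} exceeds min(n, K)={upper}")
    if k == 0:
        return TailProbability(1.0, 0.0)
    support = np.arange(k, upper + 1)
    log_p = float(logsumexp(hypergeom.logpmf(support, N, K, n)))
    log_p = min(log_p, 0.0)  # guard against rounding slightly above 1
    return TailProbability(float(math.exp(log_p)), log_p / math.log(10.0))


def overlap_significance(
    query: Iterable,
    reference_nodes: Iterable,
    universe: Union[Iterable, int],
) -> OverlapTestResult:
    """Score |query ∩ reference| against the hypergeometric null.

    ``universe`` is either an explicit symbol set (query/reference symbols
    outside it are dropped with a warning) or an integer N, in which case the
    given sets are used at face value.
    """
    query = frozenset(query)
    reference = frozenset(reference_nodes)
    if isinstance(universe, (int, np.integer)):
        N = int(universe)
        if N < 1:
            raise ValidationError("explicit universe size must be >= 1")
        q, ref = query, reference
    else:
        uni = frozenset(universe)
        if not uni:
            raise ValidationError("empty universe")
        N = len(uni)
        lost_q = len(query - uni)
        lost_r = len(reference - uni)
        if lost_q or lost_r:
            log.warning("clipped %d query and %d reference symbol(s) outside the universe",
                        lost_q, lost_r)
        q, ref = query & uni, reference & uni
    k = len(q & ref)
    n, K = len(q), len(ref)
    if max(n, K) > N:
        raise ValidationError("query/reference larger than explicit universe")
    tail = hypergeom_upper_tail(k, K, n, N)
    return OverlapTestResult(k=k, n=n, K=K, N=N, p=tail.p, log10_p=tail.log10_p)


def final_interactome(db: InteractionDB, overlap_set: Iterable) -> Network:
    """Induced subgraph of the reference interactions on the overlap set."""
    return induced_subgraph(db, overlap_set, mode="final")
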