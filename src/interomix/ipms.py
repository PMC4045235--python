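"""Cleaning of affinity-purification MS hit lists.

The cleaning protocol turns per-bait bait–prey evidence plus no-antibody
control pulldowns into a high-confidence *common interactor set*:

1. drop preys supported by fewer than ``min_peptides`` matched peptides
   (single-peptide identifications are the classic false-positive class);
2. remove every prey seen in *any* no-antibody control (bead/background
   binders) — controls carry no peptide threshold, the most stringent reading;
3. intersect the surviving per-bait prey sets, keeping only preys recovered
   with every bait.

The order is fixed: peptide filter, then background subtraction, then
intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .io import HitTable

log = logging.getLogger(__name__)

__all__ = [
    "CleaningParams",
    "CleanedSets",
    "filter_min_peptides",
    "background_union",
    "subtract_background",
    "intersect_baits",
    "clean_ipms",
]


@dataclass(frozen=True)
class CleaningParams:
    min_peptides: int = 2
    exclude_self_hits: bool = False

    def __post_init__(self) -> None:
        if self.min_peptides < 1:
            raise ValidationError("min_peptides must be >= 1")


@dataclass(frozen=True)
class CleanedSets:
    """Per-stage prey sets produced by :func:`clean_ipms`."""

    filtered: Mapping[str, frozenset]  # bait -> preys after peptide filter
    background: frozenset
    cleaned: Mapping[str, frozenset]  # bait -> preys after background subtraction
    common: frozenset

    def __post_init__(self) -> None:
        for bait, preys in self.cleaned.items():
            if not self.common <= preys:
                raise ValidationError(f"common set not contained in cleaned set for {bait}")
        if self.common & self.background:
            raise ValidationError("common set overlaps background")


def filter_min_peptides(hits: HitTable, min_peptides: int) -> frozenset:
    """Preys supported by at least ``min_peptides`` matched peptides."""
    if min_peptides < 1:
        raise ValidationError("min_peptides must be >= 1")
    rows = hits.rows
    return frozenset(rows.loc[rows["peptide_count"] >= min_peptides, "prey"])


def background_union(control_sets: Sequence[Iterable]) -> frozenset:
    """Union of all control prey sets; empty list gives the empty set."""
    out: set = set()
    for s in control_sets:
        out |= set(s)
    return frozenset(out)


def subtract_background(preys: Iterable, background: Iterable) -> frozenset:
    """Preys minus background; the result is disjoint from background."""
    return frozenset(preys) - frozenset(background)


def intersect_baits(per_bait_sets: Sequence[Iterable]) -> frozenset:
    """Preys present in every per-bait set; at least one set is required."""
    if not per_bait_sets:
        raise ValidationError("intersect_baits requires at least one prey set")
    sets = [frozenset(s) for s in per_bait_sets]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def clean_ipms(
    bait_hits: Mapping[str, HitTable],
    control_hits: Sequence[HitTable],
    params: CleaningParams = CleaningParams(),
) -> CleanedSets:
    """Run the full cleaning protocol over all baits and controls."""
    if not bait_hits:
        raise ValidationError("need at least one bait hit table")
    if not control_hits:
        log.warning("no control pulldowns supplied; background set is empty")
    filtered = {}
    for bait, hits in bait_hits.items():
        preys = filter_min_peptides(hits, params.min_peptides)
        if params.exclude_self_hits:
            preys = preys - {bait}
        filtered[bait] = preys
        log.info("%s: %d -> %d preys after >=%d-peptide filter",
                 bait, len(hits.preys), len(preys), params.min_peptides)
    # controls: any prey at any peptide count counts as background
    background = background_union([h.preys for h in control_hits])
    cleaned = {bait: subtract_background(preys, background) for bait, preys in filtered.items()}
    common = intersect_baits(list(cleaned.values()))
    log.info("background %d; per-bait cleaned %s; common %d",
             len(background), {b: len(s) for b, s in cleaned.items()}, len(common))
    return CleanedSets(filtered=filtered, background=background, cleaned=cleaned, common=common)
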