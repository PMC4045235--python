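"""Fold-change differential expression selection and probe->gene collapse.

Selection uses the ratio of group means on the linear scale:

    FC(probe) = mean(case samples) / mean(control samples)

A probe is differentially expressed at threshold t (default 2) when
FC >= t or FC <= 1/t, boundaries inclusive — the symmetric "±t fold" rule.
No variance filter or significance test is applied; fold change alone drives
the selection.  Probes collapse to genes by union: a gene is selected if any
of its probes passes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["fold_change", "select_differential", "collapse_to_genes"]


def fold_change(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe case/control fold changes on the linear scale.

    Returns a DataFrame indexed by probe with columns ``mean_case``,
    ``mean_control``, ``fold_change``, ``signed_fold`` (FC if >= 1 else
    -1/FC) and ``undefined`` (control mean is zero; such probes are excluded
    from selection and counted in the log).
    """
    values = matrix.values
    if matrix.scale == "log2":
        values = np.power(2.0, values)
    case = matrix.samples_in("case")
    control = matrix.samples_in("control")
    mean_case = values[case].mean(axis=1)
    mean_control = values[control].mean(axis=1)
    undefined = mean_control == 0
    fc = mean_case / mean_control.where(~undefined)
    signed = fc.where(fc >= 1.0, -1.0 / fc)
    if undefined.any():
        log.warning("%d probe(s) with zero control mean excluded from fold-change selection",
                    int(undefined.sum()))
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fold_change": fc,
            "signed_fold": signed,
            "undefined": undefined,
        }
    )


def select_differential(table: pd.DataFrame, threshold: float = 2.0) -> frozenset:
    """Probes with FC >= threshold or FC <= 1/threshold (boundary inclusive)."""
    if threshold <= 1:
        raise ValidationError("fold-change threshold must be > 1")
    ok = ~table["undefined"]
    fc = table["fold_change"]
    passing = ok & ((fc >= threshold) | (fc <= 1.0 / threshold))
    return frozenset(table.index[passing])


def collapse_to_genes(probes: Iterable, annotation: Mapping[str, str]) -> frozenset:
    """Distinct gene symbols of annotated probes; unannotated probes drop."""
    probes = set(probes)
    genes = {annotation[p] for p in probes if p in annotation}
    dropped = sum(1 for p in probes if p not in annotation)
    if dropped:
        log.info("%d probe(s) without gene annotation dropped in collapse", dropped)
    return frozenset(genes)
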