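"""Bundled reference tables for the 3-M syndrome disease interactome.

Two published pathway over-representation result tables for the 131-protein
3-M interactome are shipped as GMT collections, transcribed verbatim from the
printed "submitted identifiers mapping to this event" columns (including one
printed token, ``PTPB1``, that is a typographical variant of ``PTBP1``):

* ``reactome`` — Reactome-based analysis, 14 events;
* ``webgestalt`` — WebGestalt Pathway Commons analysis, 17 events.

They serve as worked examples for the enrichment machinery (the per-event
mapped-identifier counts can be recomputed from the member columns) and as a
realistic demonstration query.  The annotated pathway sizes and probabilities
printed alongside the original tables depend on service-side universes that
are not distributed, so only the membership columns are bundled.
"""

from __future__ import annotations

from importlib import resources

from .identifiers import IdentifierPolicy
from .io import GeneSetCollection, read_gmt

__all__ = ["load_reference_tables", "ANNOTATED_SIZES"]

_FILES = {
    "reactome": "reactome_3m_interactome.gmt",
    "webgestalt": "webgestalt_3m_interactome.gmt",
}

# printed annotated pathway sizes for a few frequently used events
ANNOTATED_SIZES = {
    ("reactome", "R_MRNA_SPLICING"): 112,
    ("reactome", "R_NHEJ"): 6,
    ("webgestalt", "W_GENE_EXPRESSION"): 379,
    ("webgestalt", "W_CHAPERONIN_FOLDING"): 16,
}


def load_reference_tables(policy: IdentifierPolicy | None = None) -> dict:
    """Return ``{"reactome": GeneSetCollection, "webgestalt": ...}``."""
    out = {}
    for label, fname in _FILES.items():
        ref = resources.files("interomix.data").joinpath(fname)
        with resources.as_file(ref) as path:
            out[label] = read_gmt(path, policy=policy, label=label)
    return out
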