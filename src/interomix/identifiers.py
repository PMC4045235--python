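"""Gene/protein identifier normalization.

Symbols arriving from different omics layers disagree on case, surrounding
whitespace and aliases (``p53`` vs ``TP53``; MS search-engine output vs array
annotation vs interaction-database symbols).  Every join performed by the
pipeline therefore goes through a single :class:`IdentifierPolicy`, so the
same protein is represented by the same string everywhere.

Normalization is idempotent by construction: trimming and case-folding are
idempotent, and the synonym table is resolved to fixed points when the policy
is built (alias chains are followed; cycles are rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ValidationError

__all__ = ["IdentifierPolicy", "normalize_identifier"]


@dataclass(frozen=True)
class IdentifierPolicy:
    """Rules for mapping raw identifiers to canonical symbols.

    Parameters
    ----------
    uppercase
        Case-fold symbols to upper case (gene-symbol convention).
    trim
        Strip surrounding whitespace.
    synonyms
        Optional alias -> canonical mapping.  Keys and values are themselves
        normalized (trim/case) and alias chains are collapsed, so applying
        the policy twice equals applying it once.
    """

    uppercase: bool = True
    trim: bool = True
    synonyms: Optional[Mapping[str, str]] = None
    _resolved: Mapping[str, str] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        resolved: dict[str, str] = {}
        if self.synonyms:
            base = {self._base(k): self._base(v) for k, v in self.synonyms.items()}
            for key in base:
                seen = [key]
                cur = key
                while cur in base and base[cur] != cur:
                    cur = base[cur]
                    if cur in seen:
                        raise ValidationError(
                            f"synonym cycle involving {' -> '.join(seen + [cur])}"
                        )
                    seen.append(cur)
                resolved[key] = cur
        object.__setattr__(self, "_resolved", resolved)

    def _base(self, raw: str) -> str:
        out = raw.strip() if self.trim else raw
        return out.upper() if self.uppercase else out

    def normalize(self, raw: str, *, context: str = "") -> str:
        """Return the canonical symbol for ``raw``.

        Raises
        ------
        ValidationError
            If the identifier is empty (or whitespace-only) after trimming.
        """
        if raw is None:
            raise ValidationError(f"missing identifier{_ctx(context)}")
        out = self._base(str(raw))
        if not out:
            raise ValidationError(f"empty identifier{_ctx(context)}: {raw!r}")
        return self._resolved.get(out, out)


def _ctx(context: str) -> str:
    return f" ({context})" if context else ""


def normalize_identifier(raw: str, policy: IdentifierPolicy | None = None) -> str:
    """Normalize one identifier under ``policy`` (default policy if omitted)."""
    return (policy or IdentifierPolicy()).normalize(raw)
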