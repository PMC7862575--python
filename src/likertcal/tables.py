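"""Correction-table data structures.

A correction table maps each attribute's five Likert categories to derived
interval-scale values, together with the intermediates the derivation
produced (pole extents, barycenter, neutral sign) and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .attributes import ATTRIBUTE_ORDER

__all__ = ["CorrectionRow", "CorrectionTable"]

CATEGORY_KEYS = ("dd", "d", "n", "a", "aa")


@dataclass
class CorrectionRow:
    """Derived quantities for one attribute.

    ``a0``/``d0`` are the signed agreement/disagreement pole extents, ``n0``
    the neutral interval width (absent when no neutral information was
    propagated), ``b`` the pole barycenter and ``z`` the neutral-side sign.
    ``dd, d, n, a, aa`` are the corrected values for the five categories
    (strongly disagree ... strongly agree).
    """

    a0: float
    d0: float
    n0: Optional[float]
    b: float
    z: int
    dd: float
    d: float
    n: float
    a: float
    aa: float
    n0_fallback_used: bool

    @property
    def category_values(self) -> Tuple[float, float, float, float, float]:
        """Corrected values indexed by canonical category 1..5."""
        return (self.dd, self.d, self.n, self.a, self.aa)

    def value_for(self, category: int) -> float:
        if not 1 <= int(category) <= 5:
            raise ValueError(f"category {category!r} outside [1, 5]")
        return self.category_values[int(category) - 1]

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "d0": self.d0,
            "n0": self.n0,
            "b": self.b,
            "z": self.z,
            "dd": self.dd,
            "d": self.d,
            "n": self.n,
            "a": self.a,
            "aa": self.aa,
            "n0_fallback_used": self.n0_fallback_used,
        }


@dataclass
class CorrectionTable:
    """Per-attribute corrected category values plus derivation provenance."""

    rows: Dict[str, CorrectionRow]
    anchor_node: Optional[Tuple[str, str]] = None
    anchor_value: Optional[float] = None
    edges_used: List[dict] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [a for a in ATTRIBUTE_ORDER if a not in self.rows]
        if missing:
            from .errors import MissingFieldError

            raise MissingFieldError(
                f"correction table missing attribute(s): {', '.join(missing)}"
            )

    def __getitem__(self, attribute: str) -> CorrectionRow:
        return self.rows[attribute]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CorrectionTable):
            return NotImplemented
        return all(
            self.rows[a].to_dict() == other.rows[a].to_dict()
            for a in ATTRIBUTE_ORDER
        )
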