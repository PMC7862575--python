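"""Canonical perceptual-attribute set and circumplex layout.

Eight attributes sit on a valence/arousal circumplex at 45-degree spacings;
opposing attributes form four antiparallel pairs.  Canonical Likert coding is
1 = strongly disagree ... 5 = strongly agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

__all__ = [
    "AttributeSpec",
    "ATTRIBUTES",
    "ATTRIBUTE_ORDER",
    "GROUPS",
    "NODES",
    "node_index",
    "node_name",
    "PAIRS",
]


@dataclass(frozen=True)
class AttributeSpec:
    name: str
    circumplex_angle: float  # degrees, counter-clockwise from the valence axis
    valence_polarity: int  # +1 if agreement means positive valence projection
    pair_partner: str

    def __post_init__(self) -> None:
        if self.valence_polarity not in (-1, 1):
            raise ValueError("valence_polarity must be +1 or -1")


ATTRIBUTE_ORDER: Tuple[str, ...] = (
    "pleasant",
    "annoying",
    "vibrant",
    "monotonous",
    "calm",
    "chaotic",
    "eventful",
    "uneventful",
)

_ANGLES = (0.0, 180.0, 45.0, 225.0, 315.0, 135.0, 90.0, 270.0)
_POLARITY = (1, -1, 1, -1, 1, -1, 1, -1)
_PARTNERS = (
    "annoying",
    "pleasant",
    "monotonous",
    "vibrant",
    "chaotic",
    "calm",
    "uneventful",
    "eventful",
)

ATTRIBUTES = {
    name: AttributeSpec(name, angle, pol, partner)
    for name, angle, pol, partner in zip(ATTRIBUTE_ORDER, _ANGLES, _POLARITY, _PARTNERS)
}

PAIRS: Tuple[Tuple[str, str], ...] = (
    ("pleasant", "annoying"),
    ("vibrant", "monotonous"),
    ("calm", "chaotic"),
    ("eventful", "uneventful"),
)

# Grouped-category order: disagreement, neutral, agreement.
GROUPS: Tuple[str, ...] = ("D", "N", "A")

# The 24 grouped-category variables in canonical (attribute, group) order.
NODES: Tuple[Tuple[str, str], ...] = tuple(
    (attr, grp) for attr in ATTRIBUTE_ORDER for grp in GROUPS
)

_NODE_INDEX = {node: i for i, node in enumerate(NODES)}


def node_index(node: Tuple[str, str]) -> int:
    """Canonical position of an (attribute, group) node; used for tie-breaks."""
    return _NODE_INDEX[tuple(node)]


def node_name(node: Tuple[str, str]) -> str:
    return f"{node[0]}:{node[1]}"
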