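"""Derivation of corrected Likert category values and their application.

The correction pipeline reads cross-site association structure between
grouped-category percentages as evidence about dilation or compression of
each scale's metric:

1. ``propagate_values`` anchors one grouped-category node at a fixed value
   and propagates signed values to every other node along a maximum-|r|
   spanning forest, multiplying by directional OLS slopes.
2. ``neutral_sign`` decides on which side of the barycenter each scale's
   neutral point falls, from the raw correlation of the neutral share with
   the agreement and disagreement shares.
3. ``build_correction`` turns pole extents (a0, d0), neutral width (n0) and
   neutral sign (z) into the five corrected category values.
4. ``apply_correction`` projects a record onto the corrected circumplex.

The under-determined "combine the best-correlated coefficients" step is
resolved as a greedy maximum-|r| spanning forest (Kruskal), which uses each
node's single best admissible link and guarantees a unique, cycle-free
solution.  When propagating into an unvalued node v from a valued node u,
the slope of v-on-u is used (the new value is predicted from the known one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .attributes import ATTRIBUTE_ORDER, ATTRIBUTES, NODES, node_index, node_name
from .association import (
    AssociationEdge,
    GroupedPercentages,
    admissible_edges,
    association_matrices,
    group_percentages,
)
from .errors import (
    DegenerateCorrectionError,
    DegenerateScaleError,
    DisconnectedGraphError,
    MinSitesError,
)
from .io import CodingConfig, SurveyRecord, SurveyTable
from .projection import CircumplexCoordinates
from .tables import CorrectionRow, CorrectionTable

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ANCHOR",
    "DeriveConfig",
    "PropagationResult",
    "propagate_values",
    "neutral_sign",
    "build_correction",
    "derive_correction",
    "apply_correction",
    "apply_correction_frame",
    "identity_correction",
]

Node = Tuple[str, str]

DEFAULT_ANCHOR: Tuple[Node, float] = (("pleasant", "D"), -1.0)

#: Attributes entering the corrected valence sum, all with weight +1.
VALENCE_ATTRS = ("pleasant", "annoying", "vibrant", "monotonous", "calm", "chaotic")
#: Attributes entering the corrected arousal sum with their signs.
AROUSAL_TERMS = (
    ("eventful", 1.0),
    ("uneventful", 1.0),
    ("vibrant", 1.0),
    ("monotonous", 1.0),
    ("calm", -1.0),
    ("chaotic", -1.0),
)


@dataclass(frozen=True)
class DeriveConfig:
    """Knobs of the derivation pipeline."""

    coding: CodingConfig = field(default_factory=CodingConfig)
    r_min: float = 0.7
    alpha: float = 0.05
    min_sites: int = 5
    anchor_node: Node = DEFAULT_ANCHOR[0]
    anchor_value: float = DEFAULT_ANCHOR[1]
    mode: str = "proportional"  # or "angle"

    def __post_init__(self) -> None:
        from .errors import ConfigError

        if not 0.0 < self.r_min <= 1.0:
            raise ConfigError(f"r_min must be in (0, 1], got {self.r_min}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_sites < 3:
            raise ConfigError("min_sites must be >= 3")
        if self.mode not in ("proportional", "angle"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if tuple(self.anchor_node) not in NODES:
            raise ConfigError(f"unknown anchor node {self.anchor_node!r}")
        if self.anchor_value == 0.0:
            raise ConfigError("anchor value must be nonzero")


@dataclass
class PropagationResult:
    """Signed node values propagated from the anchor over a spanning forest."""

    values: Dict[Node, float]
    unreachable: List[Node]
    spanning_edges: List[dict]  # per edge: nodes, |r|, slope used, factor
    anchor_node: Node
    anchor_value: float
    mode: str

    def value(self, node: Node) -> Optional[float]:
        return self.values.get(tuple(node))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def _dilation_factor(slope: float, mode: str) -> float:
    if mode == "proportional":
        return slope
    # "angle" mode: the slope's angle, linear in the dilation, normalized so
    # that slope +/-1 maps to a factor of +/-1.
    return math.atan(slope) / (math.pi / 4.0)


def propagate_values(
    edges: Sequence[AssociationEdge],
    anchor: Tuple[Node, float] = DEFAULT_ANCHOR,
    mode: str = "proportional",
    required_attributes: Optional[Sequence[str]] = None,
) -> PropagationResult:
    """Propagate signed values from the anchor over a max-|r| spanning forest.

    Edges are re-sorted with the deterministic admissibility ordering, so the
    result is invariant to input order.  Unreachable nodes are reported,
    never defaulted; an unreachable A or D pole of a required attribute is a
    hard error because pole extents are the derivation's primary output.
    Standalone calls require nothing (unreachable nodes are simply listed);
    the derivation pipeline requires all eight attributes.
    """
    anchor_node, anchor_value = tuple(anchor[0]), float(anchor[1])
    if not edges:
        raise DisconnectedGraphError("no admissible edges to propagate over")
    # Deduplicate by unordered node pair, keeping the largest |r|.
    best: Dict[Tuple[Node, Node], AssociationEdge] = {}
    for e in edges:
        key = (tuple(e.node_x), tuple(e.node_y))
        if key not in best or abs(e.r) > abs(best[key].r):
            best[key] = e
    ordered = sorted(
        best.values(),
        key=lambda e: (-abs(e.r), node_index(e.node_x), node_index(e.node_y)),
    )
    uf = _UnionFind(len(NODES))
    forest: Dict[Node, List[AssociationEdge]] = {nd: [] for nd in NODES}
    for e in ordered:
        if uf.union(node_index(e.node_x), node_index(e.node_y)):
            forest[tuple(e.node_x)].append(e)
            forest[tuple(e.node_y)].append(e)

    values: Dict[Node, float] = {anchor_node: anchor_value}
    spanning: List[dict] = []
    frontier = [anchor_node]
    while frontier:
        u = frontier.pop(0)
        for e in forest[u]:
            v = tuple(e.other(u))
            if v in values:
                continue
            slope = e.slope_into(v)
            factor = _dilation_factor(slope, mode)
            values[v] = values[u] * factor
            spanning.append(
                {
                    "from": node_name(u),
                    "to": node_name(v),
                    "abs_r": abs(e.r),
                    "slope": slope,
                    "factor": factor,
                }
            )
            frontier.append(v)

    unreachable = [nd for nd in NODES if nd not in values]
    required = set(required_attributes or ())
    missing_poles = sorted(
        {attr for attr, grp in unreachable if grp in ("A", "D") and attr in required},
        key=ATTRIBUTE_ORDER.index,
    )
    if missing_poles:
        raise DisconnectedGraphError(
            "pole nodes unreachable from anchor for attribute(s): "
            + ", ".join(missing_poles)
        )
    return PropagationResult(
        values=values,
        unreachable=unreachable,
        spanning_edges=spanning,
        anchor_node=anchor_node,
        anchor_value=anchor_value,
        mode=mode,
    )


def neutral_sign(gp: GroupedPercentages, attribute: str) -> int:
    """Side of the barycenter on which the neutral point sits: +1 or -1.

    +1 when the neutral share correlates at least as strongly (raw Pearson r,
    no significance filtering) with the agreement share as with the
    disagreement share; exact ties resolve to +1.  A zero-variance neutral
    series yields +1 with a logged warning; a zero-variance pole series
    contributes r = 0 to the comparison.
    """
    n = gp.series((attribute, "N"))
    if np.ptp(n) == 0.0:
        logger.warning(
            "neutral share of %r has zero variance; z defaults to +1", attribute
        )
        return 1

    def _r(other: str) -> float:
        s = gp.series((attribute, other))
        if np.ptp(s) == 0.0:
            return 0.0
        return float(np.corrcoef(n, s)[0, 1])

    return 1 if _r("A") >= _r("D") else -1


def build_correction(
    a0: float, d0: float, n0: Optional[float] = None, z: int = 1
) -> CorrectionRow:
    """Corrected category values from pole extents, neutral width and sign.

    b = (a0 + d0) / 2;  aa = a0 - b;  dd = d0 - b  (so aa = -dd);
    n = z * |b|.  With a neutral width the somewhat points sit at
    n -/+ n0/2 on the disagree/agree side of neutral (side follows the
    scale's orientation, the sign of a0 - d0); without one, equal-range
    midpoints d = (n + dd)/2 and a = (n + aa)/2 are assumed and flagged.
    """
    if z not in (-1, 1):
        raise ValueError(f"z must be +1 or -1, got {z!r}")
    if a0 == d0:
        raise DegenerateScaleError(f"zero span: a0 == d0 == {a0}")
    b = (a0 + d0) / 2.0
    aa = a0 - b
    dd = d0 - b
    n = z * abs(b)
    orient = 1.0 if a0 > d0 else -1.0
    if n0 is not None:
        n0 = abs(float(n0))
        d = n - orient * n0 / 2.0
        a = n + orient * n0 / 2.0
        fallback = False
    else:
        d = (n + dd) / 2.0
        a = (n + aa) / 2.0
        fallback = True
    return CorrectionRow(
        a0=float(a0),
        d0=float(d0),
        n0=n0,
        b=float(b),
        z=int(z),
        dd=float(dd),
        d=float(d),
        n=float(n),
        a=float(a),
        aa=float(aa),
        n0_fallback_used=fallback,
    )


def derive_correction(
    table: SurveyTable, config: Optional[DeriveConfig] = None
) -> CorrectionTable:
    """Full derivation pipeline: survey table -> corrected category values.

    Composes group_percentages -> association_matrices -> admissible_edges ->
    propagate_values -> neutral_sign -> build_correction, recording the
    anchor, the spanning edges and all soft warnings as provenance.
    Monotonicity or orientation violations warn; disconnected pole nodes and
    too few sites raise.
    """
    config = config or DeriveConfig()
    if len(set(table.frame["site_id"])) < config.min_sites:
        raise MinSitesError(
            f"need >= {config.min_sites} sites, got {len(set(table.frame['site_id']))}"
        )
    gp = group_percentages(table, config.coding)
    mats = association_matrices(gp, min_sites=config.min_sites)
    edges = admissible_edges(mats, r_min=config.r_min, alpha=config.alpha)
    prop = propagate_values(
        edges,
        anchor=(config.anchor_node, config.anchor_value),
        mode=config.mode,
        required_attributes=ATTRIBUTE_ORDER,
    )

    rows: Dict[str, CorrectionRow] = {}
    warnings: List[str] = []
    for attr in ATTRIBUTE_ORDER:
        a0 = prop.value((attr, "A"))
        d0 = prop.value((attr, "D"))
        nval = prop.value((attr, "N"))
        n0 = abs(nval) if nval is not None else None
        if n0 is None:
            warnings.append(f"{attr}: neutral node unreachable; equal-range fallback")
        z = neutral_sign(gp, attr)
        row = build_correction(a0, d0, n0, z)
        pol = ATTRIBUTES[attr].valence_polarity
        if math.copysign(1.0, row.aa) != pol:
            warnings.append(
                f"{attr}: aa sign ({row.aa:+.3g}) disagrees with valence polarity"
            )
        ordered = row.category_values if pol > 0 else tuple(reversed(row.category_values))
        if not all(x < y for x, y in zip(ordered, ordered[1:])):
            warnings.append(f"{attr}: corrected values are not strictly monotone")
        rows[attr] = row
    for w in warnings:
        logger.warning("%s", w)
    return CorrectionTable(
        rows=rows,
        anchor_node=prop.anchor_node,
        anchor_value=prop.anchor_value,
        edges_used=prop.spanning_edges,
        warnings=warnings,
    )


def _normalizers(ct: CorrectionTable) -> Tuple[float, float]:
    """Per-dimension sums of maximal sign-adjusted category values."""
    nv = sum(max(ct[a].category_values) for a in VALENCE_ATTRS)
    na = sum(max(s * v for v in ct[a].category_values) for a, s in AROUSAL_TERMS)
    if nv <= 0.0 or na <= 0.0:
        raise DegenerateCorrectionError(
            f"non-positive normalizer (valence {nv:.3g}, arousal {na:.3g})"
        )
    return nv, na


def apply_correction(record: SurveyRecord, ct: CorrectionTable) -> CircumplexCoordinates:
    """Project one record onto the corrected circumplex.

    Valence sums the corrected values of the six valence attributes; arousal
    sums the six arousal attributes with calm and chaotic negated.  Each
    dimension is normalized by the sum over its attributes of the maximum
    positive (sign-adjusted) category value, so coordinates lie in [-1, 1].
    """
    nv, na = _normalizers(ct)
    val = sum(ct[a].value_for(record.responses[a]) for a in VALENCE_ATTRS)
    aro = sum(s * ct[a].value_for(record.responses[a]) for a, s in AROUSAL_TERMS)
    return CircumplexCoordinates(val / nv, aro / na, space="corrected")


def apply_correction_frame(frame, ct: CorrectionTable):
    """Vectorized corrected projection of a canonical survey frame."""
    import pandas as pd

    nv, na = _normalizers(ct)
    val = np.zeros(len(frame))
    aro = np.zeros(len(frame))
    for a in VALENCE_ATTRS:
        lut = np.array(ct[a].category_values)
        val += lut[frame[a].to_numpy(dtype=int) - 1]
    for a, s in AROUSAL_TERMS:
        lut = np.array(ct[a].category_values)
        aro += s * lut[frame[a].to_numpy(dtype=int) - 1]
    out = pd.DataFrame({"pleasantness": val / nv, "eventfulness": aro / na})
    for col in ("respondent_id", "site_id"):
        if col in frame.columns:
            out.insert(0, col, frame[col].to_numpy())
    return out


def identity_correction() -> CorrectionTable:
    """The equidistant correction table: poles at +/-1, polarity applied.

    Positive-polarity attributes get (-1, -0.5, 0, 0.5, 1); negative ones
    the reverse.  This is the no-distortion reference table used by tests
    and simulations.
    """
    rows = {}
    for attr in ATTRIBUTE_ORDER:
        pol = ATTRIBUTES[attr].valence_polarity
        rows[attr] = build_correction(a0=1.0 * pol, d0=-1.0 * pol, n0=1.0, z=1)
    return CorrectionTable(rows=rows)
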