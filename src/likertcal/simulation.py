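"""Uniform-response simulation and exact enumeration of projected tails.

Uniform iid responses on {1..5} are projected onto the circumplex to study
the induced coordinate distribution.  ``exact_tail`` enumerates the 5**6
outcomes of the six attributes entering an axis (the other two marginalize
out) with integer counting, providing an exact oracle for the Monte-Carlo
tail fractions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .attributes import ATTRIBUTE_ORDER
from .correction import (
    AROUSAL_TERMS,
    VALENCE_ATTRS,
    _normalizers,
    apply_correction_frame,
)
from .io import SurveyTable
from .projection import ISO_WEIGHTS, NORMALIZATION, project_frame
from .tables import CorrectionTable

__all__ = ["SimulationSummary", "simulate_uniform", "exact_tail", "summarize_simulation"]

AXES = ("pleasantness", "eventfulness")


@dataclass
class AxisSummary:
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    hist_edges: Tuple[float, ...]
    hist_counts: Tuple[int, ...]
    tail_fractions: Dict[float, float] = field(default_factory=dict)


@dataclass
class SimulationSummary:
    n: int
    seed: Optional[int]
    space: str
    axes: Dict[str, AxisSummary]

    def __post_init__(self) -> None:
        for name, ax in self.axes.items():
            if sum(ax.hist_counts) != self.n:
                raise ValueError(f"{name}: histogram counts do not sum to n")
            for t, f in ax.tail_fractions.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"{name}: tail fraction at {t} outside [0, 1]")


def simulate_uniform(n: int, seed: int) -> SurveyTable:
    """n records with each attribute iid uniform on {1..5}; reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = {"site_id": ["sim"] * n, "respondent_id": [f"r{i:06d}" for i in range(n)]}
    for attr in ATTRIBUTE_ORDER:
        data[attr] = rng.integers(1, 6, size=n)
    return SurveyTable(pd.DataFrame(data))


def _axis_value_function(axis: str, space: str, ct: Optional[CorrectionTable]):
    """Per-attribute category->contribution lookups and the denominator.

    Returns (attrs, luts, denom): the six attributes the axis depends on,
    a (6, 5) array of per-category contributions, and the normalizer.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    if space == "iso":
        w = ISO_WEIGHTS[axis]
        attrs = [a for a in ATTRIBUTE_ORDER if w[a] != 0.0]
        luts = np.array([[w[a] * c for c in range(1, 6)] for a in attrs])
        return attrs, luts, NORMALIZATION
    if space == "corrected":
        if ct is None:
            raise ValueError("corrected space requires a correction table")
        nv, na = _normalizers(ct)
        if axis == "pleasantness":
            terms = [(a, 1.0) for a in VALENCE_ATTRS]
            denom = nv
        else:
            terms = list(AROUSAL_TERMS)
            denom = na
        attrs = [a for a, _ in terms]
        luts = np.array([[s * v for v in ct[a].category_values] for a, s in terms])
        return attrs, luts, denom
    raise ValueError(f"unknown space {space!r}")


def exact_tail(
    threshold: float,
    axis: str = "pleasantness",
    space: str = "iso",
    ct: Optional[CorrectionTable] = None,
) -> float:
    """Exact P(coordinate > threshold) under iid uniform responses.

    Full enumeration of the 5**6 equiprobable outcomes of the six attributes
    entering the axis; the result is an integer count over 15625.
    """
    if threshold >= 1.0:
        return 0.0
    if threshold < -1.0:
        return 1.0
    _, luts, denom = _axis_value_function(axis, space, ct)
    count = 0
    for combo in itertools.product(range(5), repeat=6):
        value = sum(luts[i][combo[i]] for i in range(6)) / denom
        if abs(value) < 1e-12:  # snap float cancellation residue to exact zero
            value = 0.0
        if value > threshold:
            count += 1
    return count / 5**6


def exact_tail_below(
    threshold: float,
    axis: str = "pleasantness",
    space: str = "iso",
    ct: Optional[CorrectionTable] = None,
) -> float:
    """Exact P(coordinate < threshold); companion oracle to exact_tail."""
    if threshold <= -1.0:
        return 0.0
    if threshold > 1.0:
        return 1.0
    _, luts, denom = _axis_value_function(axis, space, ct)
    count = 0
    for combo in itertools.product(range(5), repeat=6):
        value = sum(luts[i][combo[i]] for i in range(6)) / denom
        if abs(value) < 1e-12:
            value = 0.0
        if value < threshold:
            count += 1
    return count / 5**6


def summarize_simulation(
    table: SurveyTable,
    space: str = "iso",
    ct: Optional[CorrectionTable] = None,
    thresholds: Sequence[float] = (),
    bins: int = 50,
    seed: Optional[int] = None,
) -> SimulationSummary:
    """Project every record and summarize the per-axis distributions.

    Histograms use ``bins`` equal-width bins over [-1, 1]; tail fractions are
    the Monte-Carlo shares strictly above each requested threshold.
    """
    if space == "iso":
        coords = project_frame(table.frame)
    elif space == "corrected":
        if ct is None:
            raise ValueError("corrected space requires a correction table")
        coords = apply_correction_frame(table.frame, ct)
    else:
        raise ValueError(f"unknown space {space!r}")
    n = len(coords)
    axes: Dict[str, AxisSummary] = {}
    for axis in AXES:
        x = coords[axis].to_numpy()
        # Non-monotone correction tables can push a somewhat-point past a
        # pole; clip for binning only so counts always sum to n.
        counts, edges = np.histogram(np.clip(x, -1.0, 1.0), bins=bins, range=(-1.0, 1.0))
        axes[axis] = AxisSummary(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if n > 1 else 0.0,
            skewness=float(stats.skew(x)) if n > 1 else 0.0,
            excess_kurtosis=float(stats.kurtosis(x)) if n > 1 else 0.0,
            hist_edges=tuple(float(e) for e in edges),
            hist_counts=tuple(int(c) for c in counts),
            tail_fractions={
                float(t): float(np.mean(x > t)) for t in thresholds
            },
        )
    return SimulationSummary(n=n, seed=seed, space=space, axes=axes)
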