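"""Circumplex projection of eight-attribute responses and paired-mean fits.

The two coordinates are the orthonormal projection of the eight canonical
responses onto the valence (pleasantness) and arousal (eventfulness) axes::

    P = [(p - a) + cos45 * (ca - ch) + cos45 * (v - m)] / (4 + sqrt(32))
    E = [(e - u) + cos45 * (ch - ca) + cos45 * (v - m)] / (4 + sqrt(32))

The 1/(4 + sqrt(32)) constant is the unique normalization mapping the
extreme symmetric response pattern to +/-1, so normalized coordinates always
lie in [-1, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .attributes import ATTRIBUTE_ORDER, PAIRS
from .errors import UndefinedFitError
from .io import SurveyRecord, SurveyTable

logger = logging.getLogger(__name__)

__all__ = [
    "COS45",
    "NORMALIZATION",
    "ISO_WEIGHTS",
    "CircumplexCoordinates",
    "PairedMeansFit",
    "project_iso",
    "project_frame",
    "site_mean_profile",
    "paired_means_fit",
    "all_paired_means_fits",
]

COS45 = math.cos(math.pi / 4)
NORMALIZATION = 4.0 + math.sqrt(32.0)

#: Linear weights of each attribute in the two ISO coordinates (before the
#: 1/(4+sqrt(32)) normalization).
ISO_WEIGHTS: Dict[str, Dict[str, float]] = {
    "pleasantness": {
        "pleasant": 1.0,
        "annoying": -1.0,
        "calm": COS45,
        "chaotic": -COS45,
        "vibrant": COS45,
        "monotonous": -COS45,
        "eventful": 0.0,
        "uneventful": 0.0,
    },
    "eventfulness": {
        "eventful": 1.0,
        "uneventful": -1.0,
        "chaotic": COS45,
        "calm": -COS45,
        "vibrant": COS45,
        "monotonous": -COS45,
        "pleasant": 0.0,
        "annoying": 0.0,
    },
}


@dataclass(frozen=True)
class CircumplexCoordinates:
    pleasantness: float
    eventfulness: float
    space: str = "iso"  # "iso" or "corrected"
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.space not in ("iso", "corrected"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.normalized:
            eps = 1e-9
            if abs(self.pleasantness) > 1 + eps or abs(self.eventfulness) > 1 + eps:
                raise ValueError("normalized coordinates must lie in [-1, 1]")


@dataclass(frozen=True)
class PairedMeansFit:
    """OLS fit of the negative attribute's site means on the positive one's."""

    pair: Tuple[str, str]  # (positive, negative)
    r: float
    intercept: float
    slope: float
    n_sites: int


def project_iso(record: SurveyRecord) -> CircumplexCoordinates:
    """Project one canonical-coded record onto the ISO circumplex."""
    r = record.responses
    p = sum(ISO_WEIGHTS["pleasantness"][a] * r[a] for a in ATTRIBUTE_ORDER)
    e = sum(ISO_WEIGHTS["eventfulness"][a] * r[a] for a in ATTRIBUTE_ORDER)
    return CircumplexCoordinates(p / NORMALIZATION, e / NORMALIZATION, space="iso")


def project_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ISO projection of a canonical survey frame.

    Returns a frame with ``pleasantness`` and ``eventfulness`` columns
    (plus ``site_id``/``respondent_id`` when present in the input).
    """
    vals = frame[list(ATTRIBUTE_ORDER)].to_numpy(dtype=float)
    wp = np.array([ISO_WEIGHTS["pleasantness"][a] for a in ATTRIBUTE_ORDER])
    we = np.array([ISO_WEIGHTS["eventfulness"][a] for a in ATTRIBUTE_ORDER])
    out = pd.DataFrame(
        {
            "pleasantness": vals @ wp / NORMALIZATION,
            "eventfulness": vals @ we / NORMALIZATION,
        }
    )
    for col in ("respondent_id", "site_id"):
        if col in frame.columns:
            out.insert(0, col, frame[col].to_numpy())
    return out


def site_mean_profile(table: SurveyTable) -> Dict[str, Dict[str, float]]:
    """Arithmetic mean response per attribute per site (canonical 1-5)."""
    grouped = table.frame.groupby("site_id", sort=False)[list(ATTRIBUTE_ORDER)].mean()
    return {
        site: {a: float(grouped.loc[site, a]) for a in ATTRIBUTE_ORDER}
        for site in grouped.index
    }


def paired_means_fit(
    profiles: Mapping[str, Mapping[str, float]], pair: Tuple[str, str]
) -> PairedMeansFit:
    """Regress the negative attribute's site means on the positive one's.

    ``pair`` may list the attributes in either order; the positive-polarity
    attribute is always the regressor.  Requires >= 3 sites and non-constant
    series on both sides.
    """
    from .attributes import ATTRIBUTES

    a, b = pair
    pos, neg = (a, b) if ATTRIBUTES[a].valence_polarity == 1 else (b, a)
    sites = list(profiles)
    if len(sites) < 3:
        raise UndefinedFitError(f"paired fit needs >= 3 sites, got {len(sites)}")
    x = np.array([profiles[s][pos] for s in sites], dtype=float)
    y = np.array([profiles[s][neg] for s in sites], dtype=float)
    for name, series in ((pos, x), (neg, y)):
        if np.ptp(series) == 0.0:
            raise UndefinedFitError(f"site means of {name!r} are constant")
    fit = stats.linregress(x, y)
    return PairedMeansFit(
        pair=(pos, neg),
        r=float(fit.rvalue),
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        n_sites=len(sites),
    )


def all_paired_means_fits(table: SurveyTable) -> Dict[str, PairedMeansFit]:
    """Paired-mean diagnostics for the four opposing attribute pairs."""
    profiles = site_mean_profile(table)
    return {f"{p}-{n}": paired_means_fit(profiles, (p, n)) for p, n in PAIRS}
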