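"""Synthetic multi-site surveys from a known distorted scale metric.

A latent-response harness for end-to-end validation by parameter recovery:
each respondent holds a latent circumplex position (site mean plus bivariate
Gaussian noise); each attribute reads the projection of that position onto
its own circumplex direction, adds attribute noise, and reports the category
whose threshold interval contains the score.  Thresholds are the midpoints
of the attribute's true category values, so the stored metric IS the
distortion respondents apply.

This is the test harness's modeling assumption, not a claim about real
respondents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .attributes import ATTRIBUTE_ORDER, ATTRIBUTES
from .errors import TruthValidationError
from .io import SurveyTable
from .tables import CorrectionTable

__all__ = ["SyntheticTruth", "generate", "recovery_score", "RecoveryMetrics"]

EQUIDISTANT = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class SyntheticTruth:
    """Ground truth for the generator.

    ``category_values`` holds, per attribute, the five strictly increasing
    positions (on the attribute's own axis) that the population attaches to
    the categories; response thresholds are midpoints of adjacent values.
    Site means are latent (valence, arousal) pairs inside the unit square.
    """

    category_values: Dict[str, Tuple[float, float, float, float, float]]
    site_means: List[Tuple[float, float]]
    respondent_sd: float = 0.15
    attribute_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ATTRIBUTE_ORDER:
            if attr not in self.category_values:
                raise TruthValidationError(f"missing category values for {attr!r}")
            vals = tuple(float(v) for v in self.category_values[attr])
            if len(vals) != 5:
                raise TruthValidationError(f"{attr}: need 5 category values")
            if not all(x < y for x, y in zip(vals, vals[1:])):
                raise TruthValidationError(
                    f"{attr}: category values must be strictly increasing"
                )
            self.category_values[attr] = vals
        for v, a in self.site_means:
            if abs(v) > 1.0 or abs(a) > 1.0:
                raise TruthValidationError("site means must lie in the unit square")
        if self.respondent_sd < 0 or self.attribute_sd < 0:
            raise TruthValidationError("noise sds must be non-negative")

    def thresholds(self, attribute: str) -> Tuple[float, float, float, float]:
        vals = self.category_values[attribute]
        return tuple((vals[i] + vals[i + 1]) / 2.0 for i in range(4))

    @property
    def n_sites(self) -> int:
        return len(self.site_means)

    # -- constructors -----------------------------------------------------

    @classmethod
    def ring(
        cls,
        n_sites: int = 30,
        radius: float = 0.5,
        jitter: float = 0.05,
        respondent_sd: float = 0.15,
        attribute_sd: float = 0.1,
        seed: int = 0,
        scale_factors: Optional[Dict[str, float]] = None,
    ) -> "SyntheticTruth":
        """Site means on a ring plus jitter; optional per-scale compression.

        ``scale_factors`` multiplies an attribute's equidistant category
        values (f < 1 compresses the scale's extent by f).
        """
        rng = np.random.default_rng(seed)
        phis = np.linspace(0.0, 2.0 * math.pi, n_sites, endpoint=False)
        means = []
        for phi in phis:
            v = radius * math.cos(phi) + rng.normal(0.0, jitter)
            a = radius * math.sin(phi) + rng.normal(0.0, jitter)
            means.append((float(np.clip(v, -1, 1)), float(np.clip(a, -1, 1))))
        factors = scale_factors or {}
        values = {
            attr: tuple(factors.get(attr, 1.0) * v for v in EQUIDISTANT)
            for attr in ATTRIBUTE_ORDER
        }
        return cls(
            category_values=values,
            site_means=means,
            respondent_sd=respondent_sd,
            attribute_sd=attribute_sd,
            seed=seed,
        )

    # -- (de)serialization ------------------------------------------------

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "category_values": {a: list(v) for a, v in self.category_values.items()},
            "site_means": [list(m) for m in self.site_means],
            "respondent_sd": self.respondent_sd,
            "attribute_sd": self.attribute_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            category_values={a: tuple(v) for a, v in obj["category_values"].items()},
            site_means=[tuple(m) for m in obj["site_means"]],
            respondent_sd=float(obj["respondent_sd"]),
            attribute_sd=float(obj["attribute_sd"]),
            seed=int(obj["seed"]),
        )


def generate(truth: SyntheticTruth, respondents_per_site: int = 100) -> SurveyTable:
    """Draw a survey table from the latent-threshold model; seeded.

    The latent score of attribute i is the projection of the respondent's
    (valence, arousal) position onto the attribute's own circumplex angle
    plus attribute noise; the angle already encodes the attribute's polarity.
    """
    if truth.n_sites < 5:
        raise TruthValidationError("need >= 5 sites")
    if respondents_per_site < 10:
        raise TruthValidationError("need >= 10 respondents per site")
    rng = np.random.default_rng(truth.seed)
    n_total = truth.n_sites * respondents_per_site
    data = {
        "site_id": np.repeat(
            [f"site{idx:03d}" for idx in range(truth.n_sites)], respondents_per_site
        ),
        "respondent_id": [f"r{i:06d}" for i in range(n_total)],
    }
    means = np.repeat(np.asarray(truth.site_means, dtype=float), respondents_per_site, axis=0)
    latent = means + rng.normal(0.0, truth.respondent_sd, size=(n_total, 2))
    for attr in ATTRIBUTE_ORDER:
        theta = math.radians(ATTRIBUTES[attr].circumplex_angle)
        score = latent[:, 0] * math.cos(theta) + latent[:, 1] * math.sin(theta)
        score = score + rng.normal(0.0, truth.attribute_sd, size=n_total)
        thr = np.asarray(truth.thresholds(attr))
        data[attr] = np.searchsorted(thr, score) + 1
    return SurveyTable(pd.DataFrame(data))


@dataclass
class RecoveryMetrics:
    """How well a derived correction table matches the generating truth."""

    correlation: float  # Pearson r over the 40 aligned category values
    z_sign_agreement: int  # attributes (of 8) whose neutral side matches
    pole_ratio_error: Dict[str, float]  # per attribute, |derived - true| extent ratio
    true_aligned: Dict[str, Tuple[float, ...]] = field(repr=False, default_factory=dict)
    derived_aligned: Dict[str, Tuple[float, ...]] = field(repr=False, default_factory=dict)


def _truth_z(vals: Sequence[float]) -> int:
    b = (vals[0] + vals[4]) / 2.0
    return 1 if vals[2] - b >= 0 else -1


def recovery_score(truth: SyntheticTruth, derived: CorrectionTable) -> RecoveryMetrics:
    """Compare true and derived category values after scale alignment.

    Both sides are expressed on the attribute's own axis (derived values of
    negative-polarity attributes are polarity-flipped back) and divided by
    their pleasant agreement-pole extent, making the comparison invariant to
    the arbitrary anchor scale.
    """
    true_scale = truth.category_values["pleasant"][4]
    derived_scale = derived["pleasant"].aa
    if true_scale == 0 or derived_scale == 0:
        raise ValueError("pleasant pole extent must be nonzero for alignment")
    t_all: List[float] = []
    d_all: List[float] = []
    t_by, d_by = {}, {}
    z_agree = 0
    ratio_err: Dict[str, float] = {}
    for attr in ATTRIBUTE_ORDER:
        pol = ATTRIBUTES[attr].valence_polarity
        t_vals = tuple(v / true_scale for v in truth.category_values[attr])
        d_vals = tuple(pol * v / derived_scale for v in derived[attr].category_values)
        t_by[attr], d_by[attr] = t_vals, d_vals
        t_all.extend(t_vals)
        d_all.extend(d_vals)
        if _truth_z(t_vals) == derived[attr].z:
            z_agree += 1
        t_extent = (t_vals[4] - t_vals[0]) / 2.0
        d_extent = (d_vals[4] - d_vals[0]) / 2.0
        ratio_err[attr] = abs(d_extent - t_extent)
    corr = float(np.corrcoef(t_all, d_all)[0, 1])
    return RecoveryMetrics(
        correlation=corr,
        z_sign_agreement=z_agree,
        pole_ratio_error=ratio_err,
        true_aligned=t_by,
        derived_aligned=d_by,
    )
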