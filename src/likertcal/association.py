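"""Grouped-category percentages and cross-attribute association matrices.

Responses are collapsed per site into D/N/A percentage shares for each of
the eight attributes, giving 24 variables whose pairwise Pearson
correlations, two-sided p-values (t distribution, n-2 df) and directional
OLS slopes are computed across sites.  Edges passing the |r| and p filters
feed the metric-correction propagation.

No multiple-testing correction is applied, mirroring the source analysis;
treat per-edge p-values accordingly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .attributes import ATTRIBUTE_ORDER, GROUPS, NODES, node_index, node_name
from .errors import MinSitesError
from .io import CodingConfig, SurveyTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupedPercentages",
    "AssociationEdge",
    "AssociationMatrices",
    "group_percentages",
    "association_matrices",
    "admissible_edges",
]

Node = Tuple[str, str]


@dataclass
class GroupedPercentages:
    """Per-site D/N/A percentage shares; columns are the 24 nodes."""

    values: pd.DataFrame  # index: site_id, columns: MultiIndex (attribute, group)

    def __post_init__(self) -> None:
        expected = pd.MultiIndex.from_tuples(NODES)
        if not self.values.columns.equals(expected):
            self.values = self.values.reindex(columns=expected)
        sums = self.values.T.groupby(level=0).sum().T
        if not np.allclose(sums.to_numpy(), 100.0, atol=1e-9):
            raise ValueError("grouped percentages must sum to 100 per attribute")

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def series(self, node: Node) -> np.ndarray:
        return self.values[tuple(node)].to_numpy(dtype=float)


@dataclass(frozen=True)
class AssociationEdge:
    """Association between two grouped-category variables across sites.

    ``node_x`` precedes ``node_y`` in canonical node order.  ``beta`` is the
    angle (radians) of the y-on-x regression slope.
    """

    node_x: Node
    node_y: Node
    r: float
    p: float
    slope_y_on_x: float
    slope_x_on_y: float

    @property
    def beta(self) -> float:
        return math.atan(self.slope_y_on_x)

    def slope_into(self, target: Node) -> float:
        """Directional slope with ``target`` as the dependent variable."""
        if tuple(target) == tuple(self.node_y):
            return self.slope_y_on_x
        if tuple(target) == tuple(self.node_x):
            return self.slope_x_on_y
        raise KeyError(f"{target!r} is not an endpoint of this edge")

    def other(self, node: Node) -> Node:
        if tuple(node) == tuple(self.node_x):
            return self.node_y
        if tuple(node) == tuple(self.node_y):
            return self.node_x
        raise KeyError(f"{node!r} is not an endpoint of this edge")


@dataclass
class AssociationMatrices:
    """24x24 Pearson r, p-value and directional-slope matrices.

    ``slope.loc[i, j]`` is the OLS slope of variable i regressed on
    variable j (i dependent).  Pairs involving a zero-variance variable are
    NaN and never admissible.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    slope: pd.DataFrame
    n_sites: int

    def admissibility_mask(self, r_min: float = 0.7, alpha: float = 0.05) -> pd.DataFrame:
        mask = (self.r.abs() >= r_min) & (self.p < alpha)
        np.fill_diagonal(mask.values, False)
        return mask & self.r.notna()


def group_percentages(
    table: SurveyTable, coding: Optional[CodingConfig] = None
) -> GroupedPercentages:
    """Percentage of responses per (site, attribute) falling in D/N/A."""
    coding = coding or CodingConfig()
    frame = table.frame
    rows = {}
    for site, sub in frame.groupby("site_id", sort=False):
        if len(sub) == 0:  # defensive; groupby never yields empty groups
            logger.warning("site %s has no records; excluded", site)
            continue
        n = len(sub)
        row = {}
        for attr in ATTRIBUTE_ORDER:
            groups = sub[attr].map(coding.group_of)
            counts = groups.value_counts()
            for g in GROUPS:
                row[(attr, g)] = 100.0 * counts.get(g, 0) / n
        rows[site] = row
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = pd.MultiIndex.from_tuples(values.columns)
    values = values.reindex(columns=pd.MultiIndex.from_tuples(NODES))
    return GroupedPercentages(values)


def association_matrices(
    gp: GroupedPercentages, min_sites: int = 5
) -> AssociationMatrices:
    """Pearson r, two-sided t-test p-values and both directional OLS slopes.

    Computed via the covariance matrix; the test suite checks the result
    against an independent per-pair direct-formula oracle.
    """
    n = gp.n_sites
    if n < min_sites:
        raise MinSitesError(f"need >= {min_sites} sites, got {n}")
    X = gp.values.to_numpy(dtype=float)
    cov = np.cov(X, rowvar=False, ddof=1)
    var = np.diag(cov).copy()
    zero = var <= 0.0
    if zero.any():
        names = [node_name(NODES[i]) for i in np.flatnonzero(zero)]
        logger.warning(
            "zero-variance grouped variable(s) excluded from associations: %s",
            ", ".join(names),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(var, var))
        r = np.where(zero[:, None] | zero[None, :], np.nan, cov / denom)
        np.clip(r, -1.0, 1.0, out=r)
        # slope[i, j]: i on j  ->  cov_ij / var_j
        slope = np.where(zero[:, None] | zero[None, :], np.nan, cov / var[None, :])
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.isinf(tstat), 0.0, p))
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    labels = [node_name(nd) for nd in NODES]
    as_df = lambda m: pd.DataFrame(m, index=labels, columns=labels)  # noqa: E731
    return AssociationMatrices(r=as_df(r), p=as_df(p), slope=as_df(slope), n_sites=n)


def admissible_edges(
    m: AssociationMatrices, r_min: float = 0.7, alpha: float = 0.05
) -> List[AssociationEdge]:
    """Edges with |r| >= r_min and p < alpha, sorted by descending |r|.

    Ties break deterministically on canonical node order (attribute order,
    then D < N < A).  The magnitude filter |r| >= r_min is intentional:
    strongly negative correlations carry slope information too.
    """
    edges: List[AssociationEdge] = []
    rM, pM, sM = m.r.to_numpy(), m.p.to_numpy(), m.slope.to_numpy()
    for i in range(len(NODES)):
        for j in range(i + 1, len(NODES)):
            rij = rM[i, j]
            if np.isnan(rij) or abs(rij) < r_min or not (pM[i, j] < alpha):
                continue
            edges.append(
                AssociationEdge(
                    node_x=NODES[i],
                    node_y=NODES[j],
                    r=float(rij),
                    p=float(pM[i, j]),
                    slope_y_on_x=float(sM[j, i]),
                    slope_x_on_y=float(sM[i, j]),
                )
            )
    edges.sort(key=lambda e: (-abs(e.r), node_index(e.node_x), node_index(e.node_y)))
    return edges
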