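import math
import random

import numpy as np
import pytest

from likertcal import (
    ATTRIBUTE_ORDER,
    ATTRIBUTES,
    NODES,
    SurveyRecord,
    apply_correction,
    build_correction,
    derive_correction,
    neutral_sign,
    propagate_values,
)
from likertcal.association import AssociationEdge
from likertcal.correction import DeriveConfig, apply_correction_frame, identity_correction
from likertcal.errors import (
    ConfigError,
    DegenerateCorrectionError,
    DegenerateScaleError,
    DisconnectedGraphError,
    MinSitesError,
)
from likertcal.tables import CorrectionRow, CorrectionTable

from conftest import make_table, reciprocity_table

from test_association import filled_gp


def edge(nx, ny, r, slope_y_on_x, slope_x_on_y=None, p=1e-6):
    if slope_x_on_y is None:
        slope_x_on_y = r * r / slope_y_on_x
    return AssociationEdge(nx, ny, r=r, p=p, slope_y_on_x=slope_y_on_x, slope_x_on_y=slope_x_on_y)


PD, PN, PA = ("pleasant", "D"), ("pleasant", "N"), ("pleasant", "A")
AD, AN, AA_ = ("annoying", "D"), ("annoying", "N"), ("annoying", "A")


class TestPropagateValues:
    def test_single_edge_paper_example(self):
        edges = [edge(PD, PA, r=-0.74, slope_y_on_x=-0.74)]
        res = propagate_values(edges, anchor=(PD, -1.0))
        assert res.value(PA) == pytest.approx(0.74, abs=1e-12)
        assert res.value(PD) == -1.0

    def test_chain_product_of_slopes(self):
        edges = [
            edge(PD, AA_, r=0.97, slope_y_on_x=1.33),
            edge(AA_, AN, r=0.83, slope_y_on_x=0.5),
        ]
        res = propagate_values(edges, anchor=(PD, -1.0))
        assert res.value(AA_) == pytest.approx(-1.33, abs=1e-12)
        assert res.value(AN) == pytest.approx(-0.665, abs=1e-12)

    def test_unreached_neutral_listed(self):
        edges = [edge(PD, PA, r=-0.9, slope_y_on_x=-1.0)]
        res = propagate_values(edges, anchor=(PD, -1.0))
        assert PN in res.unreachable

    def test_missing_pole_is_hard_error(self):
        edges = [edge(PD, PA, r=-0.9, slope_y_on_x=-1.0)]
        with pytest.raises(DisconnectedGraphError, match="annoying"):
            propagate_values(
                edges, anchor=(PD, -1.0), required_attributes=("pleasant", "annoying")
            )

    def test_empty_edges_is_hard_error(self):
        with pytest.raises(DisconnectedGraphError):
            propagate_values([], anchor=(PD, -1.0))

    def test_angle_mode_factor(self):
        edges = [edge(PD, PA, r=-0.9, slope_y_on_x=-0.5)]
        res = propagate_values(edges, anchor=(PD, -1.0), mode="angle")
        assert res.value(PA) == pytest.approx(math.atan(0.5) / (math.pi / 4), abs=1e-12)

    def test_angle_mode_agrees_at_unit_slope(self):
        edges = [edge(PD, PA, r=-1.0, slope_y_on_x=-1.0)]
        for mode in ("proportional", "angle"):
            res = propagate_values(edges, anchor=(PD, -1.0), mode=mode)
            assert res.value(PA) == pytest.approx(1.0, abs=1e-12)

    def test_cycle_uses_strongest_edges(self):
        # triangle PD-PA-AD; the weakest edge (PD-AD) must be dropped
        edges = [
            edge(PD, PA, r=-0.99, slope_y_on_x=-1.0),
            edge(PA, AD, r=0.95, slope_y_on_x=2.0),
            edge(PD, AD, r=0.80, slope_y_on_x=5.0),
        ]
        res = propagate_values(edges, anchor=(PD, -1.0))
        assert res.value(AD) == pytest.approx(1.0 * 2.0, abs=1e-12)
        assert len(res.spanning_edges) == 2

    def test_order_invariance(self):
        base = [
            edge(PD, PA, r=-0.99, slope_y_on_x=-1.0),
            edge(PA, AD, r=0.95, slope_y_on_x=2.0),
            edge(PD, AD, r=0.80, slope_y_on_x=5.0),
            edge(AD, AA_, r=-0.93, slope_y_on_x=-0.7),
            edge(PA, AN, r=0.93, slope_y_on_x=0.4),
        ]
        ref = propagate_values(base, anchor=(PD, -1.0))
        rng = random.Random(0)
        for _ in range(10):
            shuffled = base[:]
            rng.shuffle(shuffled)
            res = propagate_values(shuffled, anchor=(PD, -1.0))
            assert res.values == ref.values
            assert res.spanning_edges == ref.spanning_edges

    def test_anchor_scale_invariance(self):
        edges = [
            edge(PD, PA, r=-0.99, slope_y_on_x=-1.2),
            edge(PA, AD, r=0.95, slope_y_on_x=0.8),
        ]
        one = propagate_values(edges, anchor=(PD, -1.0))
        three = propagate_values(edges, anchor=(PD, -3.0))
        for node, v in one.values.items():
            assert three.values[node] == pytest.approx(3 * v, rel=1e-12)


class TestNeutralSign:
    def test_neutral_leaning_disagreement(self):
        # neutral anticorrelates with agreement, tracks disagreement
        n = np.array([10.0, 20, 30, 40, 50])
        gp = filled_gp(
            {
                ("pleasant", "N"): n,
                ("pleasant", "A"): 80 - 1.2 * n,
                ("pleasant", "D"): 20 + 0.2 * n,
            },
            5,
        )
        assert neutral_sign(gp, "pleasant") == -1

    def test_tie_is_plus_one(self):
        n = np.array([10.0, 20, 30, 40, 50])
        gp = filled_gp(
            {
                ("pleasant", "N"): n,
                ("pleasant", "A"): 45 - 0.5 * n,
                ("pleasant", "D"): 55 - 0.5 * n,
            },
            5,
        )
        assert neutral_sign(gp, "pleasant") == 1

    def test_neutral_rises_with_agreement(self):
        n = np.array([10.0, 20, 30, 40, 50])
        gp = filled_gp(
            {
                ("pleasant", "N"): n,
                ("pleasant", "A"): 5 + 0.2 * n,
                ("pleasant", "D"): 95 - 1.2 * n,
            },
            5,
        )
        assert neutral_sign(gp, "pleasant") == 1

    def test_zero_variance_neutral_defaults_plus_one(self):
        gp = filled_gp(
            {
                ("pleasant", "N"): np.full(5, 20.0),
                ("pleasant", "A"): np.array([10.0, 20, 30, 40, 50]),
            },
            5,
        )
        assert neutral_sign(gp, "pleasant") == 1


class TestBuildCorrection:
    def test_symmetric_reduces_to_equidistant(self):
        row = build_correction(a0=1.0, d0=-1.0, n0=1.0, z=1)
        assert row.category_values == (-1.0, -0.5, 0.0, 0.5, 1.0)
        assert row.b == 0.0 and row.n0_fallback_used is False

    def test_derived_asymmetric_example(self):
        row = build_correction(a0=0.8, d0=-1.0, n0=0.3, z=-1)
        assert row.b == pytest.approx(-0.1, abs=1e-12)
        assert row.aa == pytest.approx(0.9, abs=1e-12)
        assert row.dd == pytest.approx(-0.9, abs=1e-12)
        assert row.n == pytest.approx(-0.1, abs=1e-12)
        assert row.d == pytest.approx(-0.25, abs=1e-12)
        assert row.a == pytest.approx(0.05, abs=1e-12)

    def test_fallback_midpoints(self):
        row = build_correction(a0=1.0, d0=-1.0, n0=None, z=1)
        assert row.n == 0.0
        assert row.d == pytest.approx(-0.5) and row.a == pytest.approx(0.5)
        assert row.n0_fallback_used is True

    def test_zero_span_is_error(self):
        with pytest.raises(DegenerateScaleError):
            build_correction(a0=0.5, d0=0.5)

    def test_reversed_orientation_keeps_monotone(self):
        row = build_correction(a0=-1.0, d0=1.0, n0=1.0, z=1)
        assert row.category_values == (1.0, 0.5, 0.0, -0.5, -1.0)

    @pytest.mark.parametrize(
        "a0,d0,n0,z",
        [(1, -1, 1, 1), (0.8, -1, 0.3, -1), (2, 0.5, None, 1), (-0.7, 1.1, 0.2, -1)],
    )
    def test_centering_identity(self, a0, d0, n0, z):
        row = build_correction(a0, d0, n0, z)
        assert row.aa == pytest.approx(-row.dd, abs=1e-12)


class TestDeriveCorrection:
    def test_min_sites_error(self):
        t = make_table([("s1", "r1", (3,) * 8), ("s1", "r2", (4,) * 8)])
        with pytest.raises(MinSitesError):
            derive_correction(t)

    def test_reciprocity_table_gives_equal_poles(self):
        table = reciprocity_table([0.1, 0.25, 0.4, 0.55, 0.7, 0.85])
        ct = derive_correction(table)
        for attr in ATTRIBUTE_ORDER:
            row = ct[attr]
            assert abs(row.a0) == pytest.approx(abs(row.d0), abs=1e-9)
            assert row.aa == pytest.approx(-row.dd, abs=1e-12)
            assert row.n0_fallback_used  # neutral shares have zero variance
        assert ct.anchor_node == ("pleasant", "D")

    def test_provenance_recorded(self):
        table = reciprocity_table([0.1, 0.3, 0.5, 0.7, 0.9])
        ct = derive_correction(table)
        assert len(ct.edges_used) == 15  # spanning tree over 16 pole nodes
        assert all(e["abs_r"] == pytest.approx(1.0) for e in ct.edges_used)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            DeriveConfig(r_min=0.0)
        with pytest.raises(ConfigError):
            DeriveConfig(alpha=1.5)
        with pytest.raises(ConfigError):
            DeriveConfig(mode="weird")
        with pytest.raises(ConfigError):
            DeriveConfig(anchor_node=("pleasant", "X"))


class TestApplyCorrection:
    def make_record(self, **kw):
        resp = {a: 3 for a in ATTRIBUTE_ORDER}
        resp.update(kw)
        return SurveyRecord("s", "r", resp)

    def test_identity_extreme_valence(self, identity_ct):
        rec = self.make_record(pleasant=5, annoying=1, vibrant=5, monotonous=1, calm=5, chaotic=1)
        c = apply_correction(rec, identity_ct)
        assert c.pleasantness == pytest.approx(1.0, abs=1e-12)
        assert c.space == "corrected"

    def test_identity_all_neutral(self, identity_ct):
        c = apply_correction(self.make_record(), identity_ct)
        assert c.pleasantness == 0.0 and c.eventfulness == 0.0

    def test_asymmetric_hand_computed(self):
        # one asymmetric attribute, rest identity: spreadsheet-style oracle
        rows = identity_correction().rows
        rows["pleasant"] = build_correction(a0=0.8, d0=-1.0, n0=0.3, z=-1)
        ct = CorrectionTable(rows=rows)
        rec = self.make_record(pleasant=4)  # 'somewhat agree' -> 0.05
        # valence: 0.05 + five neutrals at 0; normalizer: 0.9 + 5 * 1
        c = apply_correction(rec, ct)
        assert c.pleasantness == pytest.approx(0.05 / 5.9, abs=1e-12)

    def test_arousal_signs(self, identity_ct):
        rec = self.make_record(eventful=5, uneventful=1, calm=5, chaotic=1)
        c = apply_correction(rec, identity_ct)
        # eventful +1, uneventful(rev) +1, calm -> -(+1), chaotic -> -(-1)... net 0
        assert c.eventfulness == pytest.approx((1 + 1 - 1 - 1) / 6, abs=1e-12)

    def test_degenerate_normalizer(self):
        zero = CorrectionRow(
            a0=1, d0=-1, n0=None, b=0, z=1, dd=0, d=0, n=0, a=0, aa=0, n0_fallback_used=True
        )
        ct = CorrectionTable(rows={a: zero for a in ATTRIBUTE_ORDER})
        with pytest.raises(DegenerateCorrectionError):
            apply_correction(self.make_record(), ct)

    def test_frame_matches_scalar(self, tiny_table, identity_ct):
        coords = apply_correction_frame(tiny_table.frame, identity_ct)
        for i, rec in enumerate(tiny_table):
            c = apply_correction(rec, identity_ct)
            assert coords.loc[i, "pleasantness"] == pytest.approx(c.pleasantness, abs=1e-14)
            assert coords.loc[i, "eventfulness"] == pytest.approx(c.eventfulness, abs=1e-14)

    def test_anchor_scale_invariance_end_to_end(self):
        table = reciprocity_table([0.15, 0.3, 0.45, 0.6, 0.75, 0.9])
        ct1 = derive_correction(table)
        ct2 = derive_correction(table, DeriveConfig(anchor_value=-2.5))
        rec = next(iter(table))
        c1 = apply_correction(rec, ct1)
        c2 = apply_correction(rec, ct2)
        assert c1.pleasantness == pytest.approx(c2.pleasantness, abs=1e-12)
        assert c1.eventfulness == pytest.approx(c2.eventfulness, abs=1e-12)
        for attr in ATTRIBUTE_ORDER:
            assert ct2[attr].aa == pytest.approx(2.5 * ct1[attr].aa, rel=1e-9)
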