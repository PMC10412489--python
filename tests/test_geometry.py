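"""Vessel-tree model, I/O and synthetic generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corovast.geometry import (
    Lesion,
    LumenPoint,
    SchemaError,
    Segment,
    TreeValidationError,
    VesselTree,
    branch_chains,
    diameter_at,
    load_tree,
    make_synthetic_tree,
    percent_stenosis,
    save_tree,
)


def seg(points, seg_id="a", parent=None, outlet=True, name=None):
    return Segment(seg_id, name or seg_id, parent, np.asarray(points),
                   is_outlet=outlet)


class TestModelInvariants:
    def test_lumen_point_rejects_nonpositive_area(self):
        with pytest.raises(ValueError):
            LumenPoint(1.0, 0.0)
        with pytest.raises(ValueError):
            LumenPoint(-1.0, 1.0)

    def test_segment_needs_two_points_increasing_s(self):
        with pytest.raises(TreeValidationError):
            seg([[0.0, 1.0]])
        with pytest.raises(TreeValidationError):
            seg([[0.0, 1.0], [0.0, 1.0]])
        with pytest.raises(TreeValidationError):
            seg([[0.0, 1.0], [1.0, -2.0]])

    def test_tree_requires_single_root(self):
        with pytest.raises(TreeValidationError, match="exactly one root"):
            VesselTree([seg([[0, 1], [1, 1]], "a"),
                        seg([[0, 1], [1, 1]], "b")])

    def test_cycle_in_parent_links_rejected(self):
        a = seg([[0, 1], [1, 1]], "a", parent="b", outlet=True)
        b = seg([[0, 1], [1, 1]], "b", parent="a", outlet=True)
        root = seg([[0, 1], [1, 1]], "r")
        with pytest.raises(TreeValidationError):
            VesselTree([root, a, b])

    def test_leaf_must_be_outlet(self):
        with pytest.raises(TreeValidationError, match="outlet"):
            VesselTree([seg([[0, 1], [1, 1]], "a", outlet=False)])

    def test_empty_tree_rejected(self):
        with pytest.raises(TreeValidationError):
            VesselTree([])


class TestDiameter:
    def test_unit_area_gives_2mm(self):
        s = seg([[0, math.pi], [10, math.pi]])
        assert diameter_at(s, 4.0) == pytest.approx(2.0, rel=1e-12)

    def test_hand_inverted_area(self):
        # A = π(D/2)² with D = 4.5 mm gives A = 15.9043128 mm²
        s = seg([[0, 15.9043128], [10, 15.9043128]])
        assert diameter_at(s, 5.0) == pytest.approx(4.5, rel=1e-6)

    def test_outside_span_errors(self):
        s = seg([[0, 1], [10, 1]])
        with pytest.raises(ValueError):
            diameter_at(s, 10.5)

    def test_monotone_in_area(self):
        small = seg([[0, 2.0], [10, 2.0]])
        large = seg([[0, 3.0], [10, 3.0]])
        assert diameter_at(large, 5.0) > diameter_at(small, 5.0)


class TestPercentStenosis:
    @pytest.mark.parametrize("min_a, ref_a, expected", [
        (4.0, 4.0, 0.0),          # no narrowing
        (1.0, 4.0, 50.0),         # quarter area = half diameter
        (0.2, 5.0, 80.0),         # 4% area ratio = 80% diameter loss
    ])
    def test_diameter_convention(self, min_a, ref_a, expected):
        les = Lesion("x", 0.0, 1.0, min_a, ref_a)
        assert percent_stenosis(les) == pytest.approx(expected, abs=1e-12)

    def test_reference_below_min_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            les = Lesion("x", 0.0, 1.0, min_area=5.0,
                         reference_area_at_min=4.0)
        assert les.percent_diameter_stenosis == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3),
           ratio=st.floats(0.01, 1.0))
    def test_invariant_under_uniform_area_scaling(self, scale, ratio):
        base = Lesion("x", 0.0, 1.0, 4.0 * ratio, 4.0)
        scaled = Lesion("x", 0.0, 1.0, 4.0 * ratio * scale, 4.0 * scale)
        assert percent_stenosis(scaled) == pytest.approx(
            percent_stenosis(base), abs=1e-9)


class TestIO:
    def test_minimal_single_segment_roundtrip(self, tmp_path):
        tree = VesselTree([seg([[0.0, 7.0], [12.0, 5.0]], "only")])
        p = tmp_path / "t.json"
        save_tree(tree, p)
        back = load_tree(p)
        assert back.root_id == "only"
        assert back.segments["only"].is_outlet
        assert tree.equals(back)

    def test_roundtrip_left_tree_json_and_csv(self, tmp_path, left_healthy):
        for name in ("t.json", "t.csv"):
            p = tmp_path / name
            save_tree(left_healthy, p)
            assert left_healthy.equals(load_tree(p))

    def test_serialization_is_stable(self, tmp_path, left_healthy):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_tree(left_healthy, p1)
        save_tree(load_tree(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_schema_violation_names_field(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "corovast-tree-v1", "segments": '
                     '[{"name": "x", "points": []}]}')
        with pytest.raises(SchemaError, match="'id'"):
            load_tree(p)

    def test_wrong_format_marker_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else", "segments": []}')
        with pytest.raises(SchemaError, match="format"):
            load_tree(p)

    def test_cycle_in_file_rejected(self, tmp_path):
        p = tmp_path / "cyc.json"
        p.write_text("""
        {"format": "corovast-tree-v1", "root": "r", "segments": [
          {"id": "r", "name": "r", "parent": null,
           "points": [{"s": 0, "area": 1}, {"s": 1, "area": 1}]},
          {"id": "a", "name": "a", "parent": "b", "is_outlet": true,
           "points": [{"s": 0, "area": 1}, {"s": 1, "area": 1}]},
          {"id": "b", "name": "b", "parent": "a", "is_outlet": true,
           "points": [{"s": 0, "area": 1}, {"s": 1, "area": 1}]}
        ]}""")
        with pytest.raises(TreeValidationError):
            load_tree(p)

    def test_refuses_nonfinite_areas(self, tmp_path):
        tree = VesselTree([seg([[0.0, 1.0], [1.0, 1.0]], "only")])
        tree.segments["only"].area[0] = math.nan
        with pytest.raises(ValueError, match="non-finite"):
            save_tree(tree, tmp_path / "x.json")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_tree(tmp_path / "nope.json")


class TestGenerator:
    def test_left_template_branches(self, left_healthy):
        chains = branch_chains(left_healthy)
        assert set(chains) == {"LM", "LAD", "D1", "CX", "OM1"}
        assert left_healthy.inlet_diameter() == pytest.approx(4.32, abs=1e-9)
        # named LAD branch spans two segments around the D1 take-off
        assert len(chains["LAD"]) == 2

    def test_lesion_reaches_requested_minimum_diameter(self):
        sten, truth = make_synthetic_tree(
            "left", [("LAD", "prox", 60, 10)], seed=5)
        healthy, _ = make_synthetic_tree("left", [], seed=5)
        (les,) = truth
        s_sten = sten.segments[les.segment_id]
        s_heal = healthy.segments[les.segment_id]
        ratio = np.sqrt(s_sten.area / s_heal.area)
        assert ratio.min() == pytest.approx(0.4, abs=1e-9)
        assert les.percent_diameter_stenosis == pytest.approx(60.0, abs=1e-6)

    def test_same_seed_identical(self):
        a, _ = make_synthetic_tree("left", [("CX", 20.0, 50, 8)],
                                   noise_sd=0.05, seed=11)
        b, _ = make_synthetic_tree("left", [("CX", 20.0, 50, 8)],
                                   noise_sd=0.05, seed=11)
        assert a == b

    def test_zero_severity_is_bitwise_template(self):
        plain, _ = make_synthetic_tree("left", [], noise_sd=0.03, seed=4)
        zero, _ = make_synthetic_tree("left", [("D1", "mid", 0, 10)],
                                      noise_sd=0.03, seed=4)
        assert plain == zero

    def test_overlapping_specs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_synthetic_tree("left", [("LAD", 20.0, 50, 10),
                                         ("LAD", 25.0, 40, 10)], seed=1)

    def test_unknown_branch_and_template(self):
        with pytest.raises(ValueError, match="branch"):
            make_synthetic_tree("left", [("RCA", "prox", 50, 10)], seed=1)
        with pytest.raises(ValueError, match="template"):
            make_synthetic_tree("both", [], seed=1)

    def test_right_and_single_templates_valid(self):
        for template in ("right", "single"):
            tree, _ = make_synthetic_tree(template, [], seed=2)
            assert all(tree.segments[o].is_outlet for o in tree.outlet_ids)
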