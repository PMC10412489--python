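"""Reduced-order network solver: loss model, flow split, two-stage protocol."""

import math
import pickle

import numpy as np
import pytest

from corovast.geometry import (FluidProperties, Segment, VesselTree,
                               make_synthetic_tree)
from corovast.hemodynamics import (
    AllometricParams,
    BoundaryConditions,
    ConvergenceError,
    SolverSettings,
    allometric_inflow,
    compute_resistances,
    outlet_pressure_update,
    presimulate_flow_split,
    replace_bc,
    run_two_stage,
    segment_pressure_drop,
    solve_steady,
)
from corovast.reconstruction import detect_lesions, reconstruct_reference

from conftest import single_tube_tree, uniform_tube


def poiseuille(mu, L, Q, D):
    return 128.0 * mu * L * Q / (math.pi * D ** 4)


class TestAllometric:
    def test_operating_point(self):
        q = allometric_inflow(AllometricParams(beta=0.5, n=2, D_in=4.5))
        assert q == pytest.approx(10.125, rel=1e-12)

    def test_zero_diameter(self):
        assert allometric_inflow(AllometricParams(D_in=0.0)) == 0.0

    def test_identity_point(self):
        assert allometric_inflow(AllometricParams(beta=1, n=2, D_in=1)) == 1.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AllometricParams(beta=0.0)


class TestSegmentPressureDrop:
    def test_uniform_tube_matches_poiseuille(self):
        seg = uniform_tube(3.0, 30.0)
        Q = 2e-6
        dps, dpt = segment_pressure_drop(seg, Q)
        oracle = poiseuille(3.4e-3, 30e-3, Q, 3e-3)
        assert dpt == pytest.approx(oracle, rel=1e-9)
        assert dpt == pytest.approx(102.6, abs=0.1)
        # uniform lumen: no separation feature, no kinetic exchange
        assert dps == dpt

    def test_zero_flow(self):
        assert segment_pressure_drop(uniform_tube(3, 30), 0.0) == (0.0, 0.0)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError, match="root"):
            segment_pressure_drop(uniform_tube(3, 30), -1e-6)

    def test_quadratic_term_zero_without_feature(self):
        seg = uniform_tube(3.0, 30.0)
        d1 = segment_pressure_drop(seg, 1e-6)[1]
        d4 = segment_pressure_drop(seg, 4e-6)[1]
        assert d4 == pytest.approx(4 * d1, rel=1e-12)  # purely linear in Q

    def test_stenosis_adds_superlinear_loss(self):
        sten, _ = make_synthetic_tree("single", [("V1", "mid", 60, 10)],
                                      seed=0)
        seg = sten.segments["V1"]
        d1 = segment_pressure_drop(seg, 1e-6)[1]
        d4 = segment_pressure_drop(seg, 4e-6)[1]
        assert d4 > 4 * d1

    def test_pressure_recovery_downstream_of_throat(self):
        # static pressure rises again past the throat while total falls
        sten, _ = make_synthetic_tree("single", [("V1", "mid", 60, 10)],
                                      seed=0)
        bc = BoundaryConditions(Q_in=2e-6, Q_req={"V1": 2e-6})
        field = solve_steady(sten, bc)
        sol = field.segments["V1"]
        i_throat = int(np.argmin(sten.segments["V1"].area))
        assert np.max(sol.P[i_throat:]) > sol.P[i_throat]
        assert np.all(np.diff(sol.P_total) <= 1e-12)


def two_daughter_tree(L1=20.0, L2=40.0, D=2.0):
    """Uniform parent feeding two uniform daughters (R2 = (L2/L1)·R1)."""
    parent = Segment("p", "p", None, np.column_stack(
        [np.linspace(0, 20, 81), np.full(81, math.pi * 1.5 ** 2)]))
    d1 = Segment("d1", "d1", "p", np.column_stack(
        [np.linspace(0, L1, 81), np.full(81, math.pi * (D / 2) ** 2)]),
        is_outlet=True)
    d2 = Segment("d2", "d2", "p", np.column_stack(
        [np.linspace(0, L2, 81), np.full(81, math.pi * (D / 2) ** 2)]),
        is_outlet=True)
    return VesselTree([parent, d1, d2])


class TestFlowSplit:
    def test_symmetric_daughters_split_evenly(self):
        tree = two_daughter_tree(L1=30.0, L2=30.0)
        split = presimulate_flow_split(tree, BoundaryConditions(Q_in=4e-6))
        assert split["d1"] == pytest.approx(split["d2"], rel=1e-5)

    def test_doubled_resistance_gives_2_to_1(self):
        # linear-network oracle: flows inverse to viscous resistance
        tree = two_daughter_tree(L1=20.0, L2=40.0)
        split = presimulate_flow_split(tree, BoundaryConditions(Q_in=3e-6))
        assert split["d1"] / split["d2"] == pytest.approx(2.0, rel=1e-4)

    def test_single_segment_gets_full_inflow(self):
        tree = single_tube_tree()
        split = presimulate_flow_split(tree, BoundaryConditions(Q_in=5e-6))
        assert split["tube"] == pytest.approx(5e-6, rel=1e-12)

    def test_split_sums_to_inflow(self, left_healthy):
        q_in = 10.125e-6
        split = presimulate_flow_split(left_healthy,
                                       BoundaryConditions(Q_in=q_in))
        assert sum(split.values()) == pytest.approx(q_in, rel=1e-12)

    def test_requires_positive_inflow(self, left_healthy):
        with pytest.raises(ValueError, match="Q_in"):
            presimulate_flow_split(left_healthy, BoundaryConditions())

    def test_nonconvergence_raises_with_history(self, left_healthy):
        settings = SolverSettings(tolerance=1e-14, max_iterations=2)
        with pytest.raises(ConvergenceError) as exc:
            presimulate_flow_split(left_healthy,
                                   BoundaryConditions(Q_in=1e-5), None,
                                   settings)
        assert len(exc.value.residual_history) == 2


class TestResistancesAndOutletUpdate:
    def test_resistance_hand_value(self):
        # (12.8 kPa − 2.8 kPa) / 2 ml/s = 5 kPa·s/ml = 5e9 Pa·s/m³
        r = compute_resistances({"o": 12800.0}, {"o": 2e-6}, 2800.0)
        assert r["o"] == pytest.approx(5e9, rel=1e-12)

    def test_outlet_at_zero_flow_pressure_has_zero_resistance(self):
        assert compute_resistances({"o": 2800.0}, {"o": 1e-6},
                                   2800.0)["o"] == 0.0

    def test_zero_flow_is_error(self):
        with pytest.raises(ZeroDivisionError):
            compute_resistances({"o": 1e4}, {"o": 0.0}, 2800.0)

    def test_converged_outlet_needs_no_update(self):
        assert outlet_pressure_update(1.0, 1.0, 1.0, 1.0) == 0.0

    def test_direct_substitution(self):
        assert outlet_pressure_update(2.0, 0.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_excess_flow_raises_back_pressure(self):
        assert outlet_pressure_update(2e-3, 1e-3, 1e-6, 1056.0) > 0.0
        assert outlet_pressure_update(1e-3, 2e-3, 1e-6, 1056.0) < 0.0


class TestSolveSteady:
    def test_single_tube_outlet_pressure(self):
        tree = single_tube_tree(3.0, 30.0)
        Q = 2e-6
        bc = BoundaryConditions(Q_in=Q, Q_req={"tube": Q})
        field = solve_steady(tree, bc)
        oracle = poiseuille(3.4e-3, 30e-3, Q, 3e-3)
        assert field.outlet_pressure["tube"] == pytest.approx(
            26000.0 - oracle, rel=1e-12)
        # pressure falls linearly in s for a uniform lumen
        sol = field.segments["tube"]
        assert np.allclose(np.diff(sol.P), np.diff(sol.P)[0], rtol=1e-9)

    def test_stage2_reproduces_stage1_outlet_pressures(self, left_healthy):
        bc = BoundaryConditions(Q_in=10.125e-6)
        split = presimulate_flow_split(left_healthy, bc)
        bc2 = replace_bc(bc, P_a=split.inlet_pressure, Q_req=dict(split))
        field = solve_steady(left_healthy, bc2)
        for oid, p in field.outlet_pressure.items():
            assert p == pytest.approx(2800.0, abs=10 * 1e-5 * 2800.0)

    def test_pressure_outlet_mode_matches_prescribed_flows(self, left_healthy):
        bc = BoundaryConditions(Q_in=10.125e-6)
        split = presimulate_flow_split(left_healthy, bc)
        bc2 = replace_bc(bc, Q_req=dict(split))
        direct = solve_steady(left_healthy, bc2, mode="prescribed_flows")
        iterated = solve_steady(left_healthy, bc2, mode="pressure_outlets")
        for oid in direct.outlet_pressure:
            assert iterated.outlet_pressure[oid] == pytest.approx(
                direct.outlet_pressure[oid], rel=10 * 1e-5)

    def test_mass_conserved_at_every_junction(self, left_healthy):
        bc = BoundaryConditions(Q_in=10.125e-6)
        split = presimulate_flow_split(left_healthy, bc)
        field = solve_steady(left_healthy, replace_bc(bc, Q_req=dict(split)))
        for sid in left_healthy.segments:
            kids = left_healthy.children(sid)
            if kids:
                assert field.segments[sid].Q == pytest.approx(
                    sum(field.segments[k.id].Q for k in kids), rel=1e-12)

    def test_total_pressure_monotone_along_flow(self, d1_result):
        for field in (d1_result.field_sten, d1_result.field_rec):
            for sol in field.segments.values():
                assert np.all(np.diff(sol.P_total) <= 1e-9)

    def test_missing_outlet_target_rejected(self, left_healthy):
        bc = BoundaryConditions(Q_in=1e-6, Q_req={"D1": 1e-6})
        with pytest.raises(ValueError, match="outlet"):
            solve_steady(left_healthy, bc)


class TestTwoStage:
    def test_identical_pair_gives_identical_fields(self, left_healthy):
        f_sten, f_rec, bc = run_two_stage(left_healthy, left_healthy)
        for sid in left_healthy.segments:
            assert np.array_equal(f_sten.segments[sid].P,
                                  f_rec.segments[sid].P)
        assert bc.Q_in == pytest.approx(
            allometric_inflow(AllometricParams(D_in=4.32)) * 1e-6)

    def test_lesion_lowers_distal_pressure_only_downstream(self, d1_pair):
        sten, healthy, truth = d1_pair
        f_sten, f_rec, _ = run_two_stage(sten, healthy)
        assert f_sten.outlet_pressure["D1"] < f_rec.outlet_pressure["D1"]
        for sibling in ("CX_d", "OM1", "LAD_d"):
            assert f_sten.outlet_pressure[sibling] == pytest.approx(
                f_rec.outlet_pressure[sibling], rel=1e-14)

    def test_doubling_k_sep_increases_stenotic_drop_only(self, d1_pair):
        sten, healthy, _ = d1_pair
        base = run_two_stage(sten, healthy,
                             settings=SolverSettings(K_sep=1.0))
        double = run_two_stage(sten, healthy,
                               settings=SolverSettings(K_sep=2.0))
        assert double[0].outlet_pressure["D1"] < base[0].outlet_pressure["D1"]
        # reference tree has no converging–diverging feature: unchanged
        assert double[1].outlet_pressure["D1"] == pytest.approx(
            base[1].outlet_pressure["D1"], rel=1e-12)

    def test_resistances_positive_and_consistent(self, d1_pair):
        sten, healthy, _ = d1_pair
        _, f_rec, bc = run_two_stage(sten, healthy)
        for oid, r in bc.R.items():
            assert r > 0
            assert r == pytest.approx(
                (f_rec.outlet_pressure[oid] - bc.P0) / bc.Q_req[oid])

    def test_unpaired_trees_rejected(self, d1_pair):
        sten, _, _ = d1_pair
        other, _ = make_synthetic_tree("right", [], seed=1)
        with pytest.raises(ValueError, match="paired"):
            run_two_stage(sten, other)

    def test_two_stage_deterministic_bitwise(self, d1_pair):
        sten, healthy, _ = d1_pair
        a = run_two_stage(sten, healthy)
        b = run_two_stage(sten, healthy)
        assert pickle.dumps(a) == pickle.dumps(b)


def test_reynolds_in_laminar_to_transitional_range(left_healthy):
    # ~10 ml/s through a 4.32 mm inlet: Re well below fully turbulent
    f_sten, _, _ = run_two_stage(left_healthy, left_healthy)
    re_max = max(s.reynolds_max for s in f_sten.segments.values())
    assert 500 < re_max < 3500
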