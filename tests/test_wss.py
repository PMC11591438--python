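"""WSS extraction and the projected-coverage objective."""

import numpy as np
import pytest

from microtrench.fem import Q2Q1Space
from microtrench.flow import FlowConditions, FlowField, solve_navier_stokes, \
    solve_steady_flow
from microtrench.geometry import BLOOD, ChannelSpec, make_trench_design
from microtrench.meshing import generate_mesh
from microtrench.wss import (CoverageResult, WSSBandThresholds, WSSProfile,
                             classify_band, coverage_objective,
                             wall_shear_stress)

THR = WSSBandThresholds()


class TestClassifyBand:
    @pytest.mark.parametrize("tau,expected", [
        (30.0, "in"),
        (10.0, "below"),   # strict: boundary value is out of band
        (50.0, "above"),
        (9.999, "below"),
        (10.001, "in"),
        (0.0, "below"),
        (1e6, "above"),
    ])
    def test_strict_inequalities(self, tau, expected):
        assert classify_band(tau, THR) == expected

    def test_vectorized(self):
        out = classify_band(np.array([5.0, 30.0, 500.0]), THR)
        assert list(out) == ["below", "in", "above"]

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            WSSBandThresholds(lower=50.0, upper=10.0)


def synthetic_profile(taus, weights, cls="trench-floor"):
    n = len(taus)
    w = np.asarray(weights, dtype=float)
    return WSSProfile(
        arc=np.cumsum(w) - w / 2, x=np.cumsum(w) - w / 2,
        seg_class=np.array([cls] * n), seg_id=np.zeros(n, dtype=int),
        tau=np.asarray(taus, dtype=float), weight_dx=w, weight_arc=w)


class TestCoverageObjective:
    def test_uniform_in_band_gives_one(self):
        cov = coverage_objective(synthetic_profile([30.0] * 5, [1.0] * 5))
        assert cov.f == 1.0

    def test_uniform_below_band_gives_zero(self):
        cov = coverage_objective(synthetic_profile([5.0] * 5, [1.0] * 5))
        assert cov.f == 0.0
        assert cov.length_below == pytest.approx(5.0)

    def test_hand_weighted_half_split(self):
        # half the projected length at tau=30 (in), half at 200 (above)
        cov = coverage_objective(synthetic_profile([30.0, 200.0], [2.0, 2.0]))
        assert cov.f == pytest.approx(0.5)
        assert cov.length_above == pytest.approx(2.0)

    def test_band_lengths_partition_total(self, frendl_wss):
        cov = coverage_objective(frendl_wss)
        assert (cov.length_in + cov.length_below + cov.length_above
                == pytest.approx(cov.total_projected, rel=1e-12))
        assert 0.0 <= cov.f <= 1.0

    def test_zero_projected_region_raises(self, frendl_wss):
        # vertical sidewalls project to zero length
        with pytest.raises(ValueError):
            coverage_objective(frendl_wss, THR, region=("sidewall-down",))

    def test_unknown_region_label(self, frendl_wss):
        cov_all = coverage_objective(frendl_wss, THR, region="all")
        cov_pat = coverage_objective(frendl_wss, THR, region="patterned")
        # flats at bulk shear are above-band, diluting the all-region f
        assert cov_all.total_projected > cov_pat.total_projected


class TestWallShearExtraction:
    def test_refuses_non_converged_flow(self, frendl_flow):
        _, mesh, flow = frendl_flow
        bad = FlowField(mesh, flow.space, flow.velocity, flow.pressure,
                        [], converged=False, fluid=flow.fluid)
        with pytest.raises(ValueError, match="converged"):
            wall_shear_stress(bad)

    def test_vertical_sidewalls_zero_projection(self, frendl_wss):
        m = np.char.startswith(frendl_wss.seg_class.astype(str), "sidewall")
        assert np.all(frendl_wss.weight_dx[m] < 1e-15)
        assert np.all(frendl_wss.weight_arc[m] > 0)

    def test_trapezoid_sidewall_projection_is_h_tan_alpha(self):
        d = make_trench_design("trapezoidal", 150e-6, 110e-6, 45.0, 0.0, 1)
        ch = ChannelSpec(0.508e-3, 1.5e-3, 1.5e-3)
        mesh = generate_mesh(d, ch, "sweep")
        flow = solve_steady_flow(mesh, BLOOD,
                                 FlowConditions(target_bulk_wss=600.0))
        wss = wall_shear_stress(flow)
        m = wss.seg_class == "sidewall-down"
        assert wss.weight_dx[m].sum() == pytest.approx(150e-6, rel=1e-9)

    def test_sample_weights_sum_to_segment_projection(self, frendl_flow,
                                                      frendl_wss):
        _, mesh, _ = frendl_flow
        for sid, seg in enumerate(mesh.profile.segments):
            m = frendl_wss.seg_id == sid
            assert frendl_wss.weight_dx[m].sum() == pytest.approx(
                seg.dx, abs=1e-12)
            assert frendl_wss.weight_arc[m].sum() == pytest.approx(
                seg.length, rel=1e-9)

    def test_floor_throttled_two_orders_of_magnitude(self, frendl_wss):
        """Deep vertical trenches cut floor WSS by >100x below bulk."""
        assert frendl_wss.class_mean("trench-floor") < 600.0 / 100.0

    def test_trench_bottom_corners_below_band(self):
        """The floor corners of a trapezoidal trench sit below 10 dyn/cm^2."""
        d = make_trench_design("trapezoidal", 150e-6, 110e-6, 45.0, 0.0, 3)
        ch = ChannelSpec(0.508e-3, 1.5e-3, 2.0e-3)
        mesh = generate_mesh(d, ch, "coarse")
        flow = solve_steady_flow(mesh, BLOOD,
                                 FlowConditions(target_bulk_wss=600.0))
        wss = wall_shear_stress(flow)
        for sid in np.unique(wss.seg_id[wss.seg_class == "trench-floor"]):
            m = wss.seg_id == sid
            tau = wss.tau[m]
            assert tau[0] < 10.0 and tau[-1] < 10.0

    def test_couette_flow_analytic_shear(self):
        """Plane Couette (moving top wall): tau = mu * U / h everywhere."""
        ch = ChannelSpec(0.5e-3, 1.0e-3, 1.0e-3)
        mesh = generate_mesh(None, ch, "sweep")
        space = Q2Q1Space(mesh)
        U, H = 0.05, 0.5e-3
        n2 = space.n2
        y = space.q2_coords[:, 1]
        lid = space.nodes_on_edges(mesh.top_edges, "q2")
        floor = space.nodes_on_edges(mesh.wetted_edges[:, :2], "q2")
        inlet = space.nodes_on_edges(mesh.inlet_edges, "q2")
        dmap = {int(i): U * y[i] / H for i in inlet}
        for i in lid:
            dmap[int(i)] = U
        for i in floor:
            dmap[int(i)] = 0.0
        u_idx = np.array(sorted(dmap))
        vnod = np.unique(np.concatenate([lid, floor, inlet]))
        vel, p, hist, ok = solve_navier_stokes(
            space, BLOOD.viscosity, BLOOD.density,
            np.concatenate([u_idx, n2 + vnod]),
            np.concatenate([np.array([dmap[i] for i in u_idx]),
                            np.zeros(len(vnod))]),
            u_scale=U)
        assert ok
        flow = FlowField(mesh, space, vel, p, hist, True, U, 0.0, BLOOD)
        wss = wall_shear_stress(flow)
        expected = BLOOD.viscosity * U / H * 10.0   # dyn/cm^2
        assert np.all(np.abs(wss.tau / expected - 1.0) < 1e-6)

    def test_boundary_sampling_refinement_invariance(self):
        """With the flow field fixed, refining the boundary quadrature
        changes f by < 2%."""
        d = make_trench_design("trapezoidal", 0.79e-3, 1.6e-3, 51.8, 0.0, 3)
        ht = 0.508e-3 + d.height
        ch = ChannelSpec(0.508e-3, max(1.5e-3, ht), max(2e-3, 2 * ht))
        mesh = generate_mesh(d, ch, "sweep")
        flow = solve_steady_flow(mesh, BLOOD,
                                 FlowConditions(target_bulk_wss=600.0))
        f2 = coverage_objective(wall_shear_stress(flow, npts=2)).f
        f3 = coverage_objective(wall_shear_stress(flow, npts=3)).f
        assert abs(f3 - f2) / f2 < 0.02
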