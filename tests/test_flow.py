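"""Steady flow solver: analytic anchors, benchmark, conservation, guards."""

import numpy as np
import pytest

from microtrench.flow import (FlowConditions, inlet_velocity_for_bulk_wss,
                              solve_lid_driven_cavity, solve_steady_flow)
from microtrench.geometry import BLOOD, ChannelSpec, make_trench_design
from microtrench.meshing import generate_mesh
from microtrench.wss import wall_shear_stress


class TestInletVelocity:
    def test_closed_form_example(self):
        # 600 dyn/cm^2 in a 0.508 mm channel of 3.5 cP blood
        u = inlet_velocity_for_bulk_wss(600.0, 0.508e-3, 3.5e-3)
        assert u == pytest.approx(60.0 * 0.508e-3 / (6 * 3.5e-3), rel=1e-12)
        assert u == pytest.approx(1.4514, rel=1e-3)

    def test_zero_target_gives_zero_velocity(self):
        assert inlet_velocity_for_bulk_wss(0.0, 0.508e-3, 3.5e-3) == 0.0

    def test_linear_in_height(self):
        u1 = inlet_velocity_for_bulk_wss(600.0, 0.508e-3, 3.5e-3)
        u2 = inlet_velocity_for_bulk_wss(600.0, 0.254e-3, 3.5e-3)
        assert u2 == pytest.approx(u1 / 2)

    def test_conditions_require_exactly_one_spec(self):
        with pytest.raises(ValueError):
            FlowConditions()
        with pytest.raises(ValueError):
            FlowConditions(inlet_mean_velocity=1.0, target_bulk_wss=600.0)


class TestPlanePoiseuille:
    @pytest.mark.parametrize("height,target", [
        (0.2e-3, 600.0), (0.508e-3, 600.0), (2.0e-3, 100.0)])
    def test_wall_shear_within_one_percent(self, height, target):
        # target scaled down at the largest height to stay in the laminar
        # regime; heights span a decade
        ch = ChannelSpec(height, 3 * height, 3 * height)
        mesh = generate_mesh(None, ch, "coarse")
        flow = solve_steady_flow(mesh, BLOOD,
                                 FlowConditions(target_bulk_wss=target))
        wss = wall_shear_stress(flow)
        assert np.all(np.abs(wss.tau / target - 1.0) < 0.01)

    def test_centerline_velocity_is_1p5_mean(self):
        ch = ChannelSpec(0.508e-3, 1.5e-3, 1.5e-3)
        mesh = generate_mesh(None, ch, "coarse")
        flow = solve_steady_flow(mesh, BLOOD,
                                 FlowConditions(inlet_mean_velocity=0.5))
        space = flow.space
        xy = space.q2_coords
        mid = np.argmin(np.abs(xy[:, 0] - 3.2e-3)**2
                        + np.abs(xy[:, 1] - 0.254e-3)**2)
        assert flow.velocity[mid, 0] == pytest.approx(0.75, rel=0.01)

    def test_tau_scales_inverse_height_over_decade(self):
        """At fixed mean velocity, fully developed WSS ~ 1/h."""
        U = 0.3
        taus, heights = [], [0.3e-3, 0.6e-3, 1.2e-3, 3.0e-3]
        for h in heights:
            ch = ChannelSpec(h, 3 * h, 3 * h)
            mesh = generate_mesh(None, ch, "coarse")
            flow = solve_steady_flow(mesh, BLOOD,
                                     FlowConditions(inlet_mean_velocity=U))
            taus.append(wall_shear_stress(flow).tau.mean())
        products = np.array(taus) * np.array(heights)
        assert np.all(np.abs(products / products[0] - 1.0) < 0.01)


class TestSolverBehaviour:
    def test_mass_conservation(self, frendl_flow):
        _, _, flow = frendl_flow
        assert flow.mass_flux_imbalance() < 1e-6

    def test_residual_history_converged(self, frendl_flow):
        _, _, flow = frendl_flow
        assert flow.converged
        last = flow.residual_history[-1]
        assert last["r_mom"] < 1e-6 and last["r_cont"] < 1e-6

    def test_bit_identical_reruns(self):
        """Same mesh + conditions give byte-identical solutions and
        residual histories (fixed iteration order, direct solves)."""
        d = make_trench_design("trapezoidal", 150e-6, 110e-6, 45.0, 0.0, 3)
        ch = ChannelSpec(0.508e-3, 1.5e-3, 2.0e-3)
        results = []
        for _ in range(2):
            mesh = generate_mesh(d, ch, "sweep")
            flow = solve_steady_flow(mesh, BLOOD,
                                     FlowConditions(target_bulk_wss=600.0))
            results.append(flow)
        a, b = results
        assert np.array_equal(a.velocity, b.velocity)
        assert a.residual_history == b.residual_history

    def test_trench_vortex_has_circulation(self, frendl_flow):
        """Deep vertical trenches hold a recirculating vortex."""
        _, _, flow = frendl_flow
        h, w = 700e-6, 400e-6
        gamma = flow.trench_circulation()
        assert abs(gamma) > 1e-3 * flow.mean_velocity * min(h, w)

    def test_reynolds_guard_refuses_turbulent_regime(self):
        ch = ChannelSpec(5e-3, 15e-3, 15e-3)
        mesh = generate_mesh(None, ch, "sweep")
        with pytest.raises(ValueError, match="laminar"):
            solve_steady_flow(mesh, BLOOD, FlowConditions(inlet_mean_velocity=2.0))

    def test_uniform_inlet_requires_entrance_length(self):
        ch = ChannelSpec(0.508e-3, 0.5e-3, 2.0e-3)   # far below 0.05*Re*h
        mesh = generate_mesh(None, ch, "sweep")
        with pytest.raises(ValueError, match="entrance"):
            solve_steady_flow(mesh, BLOOD,
                              FlowConditions(target_bulk_wss=600.0,
                                             inlet_profile="uniform"))

    def test_zero_velocity_shortcut(self):
        ch = ChannelSpec(0.508e-3, 1.5e-3, 1.5e-3)
        mesh = generate_mesh(None, ch, "sweep")
        flow = solve_steady_flow(mesh, BLOOD,
                                 FlowConditions(inlet_mean_velocity=0.0))
        assert flow.converged and np.all(flow.velocity == 0.0)


class TestLidDrivenCavity:
    def test_primary_vortex_matches_reference(self):
        """Unit cavity at Re=100: primary vortex at (0.617, 0.734) with
        streamfunction minimum -0.1034 (classic fine-grid benchmark)."""
        _, center, psi_min = solve_lid_driven_cavity(40, 100.0)
        assert center[0] == pytest.approx(0.6172, abs=0.03)
        assert center[1] == pytest.approx(0.7344, abs=0.03)
        assert psi_min == pytest.approx(-0.10342, rel=0.05)


class TestCreepingFlow:
    def test_symmetric_trench_wss_fore_aft_symmetric(self):
        """At Re << 1 the flow is reversible: the in-trench WSS profile of a
        symmetric single trench is fore-aft symmetric within 2%."""
        d = make_trench_design("trapezoidal", 150e-6, 110e-6, 45.0, 0.0, 1)
        ch = ChannelSpec(0.508e-3, 1.5e-3, 1.5e-3)
        mesh = generate_mesh(d, ch, "coarse")
        U = 1e-4   # Re ~ 1.5e-2
        flow = solve_steady_flow(mesh, BLOOD,
                                 FlowConditions(inlet_mean_velocity=U))
        wss = wall_shear_stress(flow)
        sel = np.isin(wss.seg_class,
                      ("sidewall-down", "trench-floor", "sidewall-up"))
        tau = wss.tau[sel]
        # mesh and quadrature are symmetric, so reversal maps samples 1:1
        rel = np.abs(tau - tau[::-1]) / tau.max()
        assert np.all(rel < 0.02)


class TestGridConvergence:
    def test_objective_stable_between_medium_and_fine(self):
        """Solver contract: the coverage objective changes by less than two
        percentage points of coverage between the medium and fine meshes
        (checked on a large trapezoidal trench whose in-band strips are
        well resolved)."""
        from microtrench.optimizer import CoverageEvaluator
        fm = CoverageEvaluator(resolution="medium")(0.79e-3, 1.6e-3, 51.8)
        ff = CoverageEvaluator(resolution="fine")(0.79e-3, 1.6e-3, 51.8)
        assert abs(ff - fm) < 0.02
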