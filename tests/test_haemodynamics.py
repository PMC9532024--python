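"""Solver primitives: conductance, wall mechanics, Kirchhoff solves."""

import numpy as np
import pytest
import collateralflow as cf
from collateralflow.haemodynamics import (FlowModel, assemble_and_solve,
                                          conductance, distensibility,
                                          radius_from_pressure, wall_thickness)


class TestConductance:
    def test_poiseuille_limit(self):
        # zeta = 2 must reproduce the textbook hydraulic law pi r^4/(8 mu L)
        r, length, mu = 0.5, 7.0, 3.5e-3
        g = conductance(r, length, mu, zeta=2.0)
        expected = np.pi * (r * 1e-3) ** 4 / (8 * mu * length * 1e-3)
        assert g == expected

    def test_scaling_laws(self):
        g = conductance(0.3, 5.0, 3.5e-3, 9.0)
        assert conductance(0.3, 10.0, 3.5e-3, 9.0) == pytest.approx(g / 2)
        assert conductance(0.6, 5.0, 3.5e-3, 9.0) == pytest.approx(16 * g)

    def test_blunt_profile_value(self):
        # oracle: direct SI evaluation of pi r^4 / (2 (zeta+2) mu L)
        expected = np.pi * (2e-4) ** 4 / (2 * 11 * 3.5e-3 * 2e-3)
        assert conductance(0.2, 2.0, 3.5e-3, 9.0) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(3.26e-11, rel=1e-2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            conductance(-0.1, 1.0, 3.5e-3, 9.0)
        with pytest.raises(ValueError):
            conductance(0.1, 1.0, 3.5e-3, -1.0)


class TestWallMechanics:
    def test_thin_vessel_limit(self):
        # h/r0 -> a + c = 0.4126 as r0 -> 0
        assert wall_thickness(1e-9) / 1e-9 == pytest.approx(0.4126, abs=1e-4)

    def test_pial_wall_thickness(self):
        assert wall_thickness(0.2) == pytest.approx(0.0771, abs=2e-4)

    def test_monotone_increasing(self):
        r = np.linspace(1e-3, 1.0, 500)
        h = wall_thickness(r)
        assert np.all(np.diff(h) > 0)

    def test_reference_state(self):
        h = wall_thickness(0.2)
        r = radius_from_pressure(1e4, 1e4, 0.2, 1.6e6, h, 0.5)
        assert r == pytest.approx(0.2, rel=1e-14)

    def test_slope_matches_distensibility(self):
        # dr/dP = r0^2 (1-nu^2)/(E h); D = 2 (1-nu^2) r0^2/(r E h)
        r0, E, nu = 0.2, 1.6e6, 0.5
        h = wall_thickness(r0)
        dP = 10.0
        r1 = radius_from_pressure(1e4, 1e4 - dP, r0, E, h, nu)
        slope = (r1 - r0) * 1e-3 / dP
        expected = (r0 * 1e-3) ** 2 * (1 - nu ** 2) / (E * h * 1e-3)
        assert slope == pytest.approx(expected, rel=1e-9)
        d = distensibility(r0, r0, E, h, nu)
        assert d == pytest.approx(2 * (1 - nu ** 2) * (r0 * 1e-3) / (E * h * 1e-3))

    def test_collapse_reported(self):
        with pytest.raises(cf.haemodynamics.CollapseError):
            radius_from_pressure(-1e9, 1e4, 0.2, 1.6e6, wall_thickness(0.2), 0.5)


class TestAssembleAndSolve:
    def test_series_midpoint_is_mean(self):
        p = assemble_and_solve(3, [(0, 1), (1, 2)], [1e-9, 1e-9],
                               pinned={0: 1000.0, 2: 500.0})
        assert p[1] == pytest.approx(750.0)

    def test_equal_boundaries_equilibrium(self):
        rng = np.random.default_rng(0)
        edges = [(i, i + 1) for i in range(9)] + [(0, 5), (2, 8)]
        g = rng.uniform(1e-10, 1e-8, len(edges))
        p = assemble_and_solve(10, edges, g, pinned={0: 800.0, 9: 800.0})
        assert np.allclose(p, 800.0, rtol=1e-12)

    def test_matches_dense_oracle(self):
        # independent oracle: dense Laplacian + numpy solve on a random graph
        rng = np.random.default_rng(42)
        n = 20
        edges = [(i, rng.integers(0, i)) for i in range(1, n)]
        edges += [tuple(rng.choice(n, 2, replace=False)) for _ in range(15)]
        g = rng.uniform(1e-11, 1e-8, len(edges))
        pinned = {0: 12_000.0, n - 1: 700.0, 7: 5_000.0}
        dense = np.zeros((n, n))
        for (a, b), gi in zip(edges, g):
            dense[a, a] += gi
            dense[b, b] += gi
            dense[a, b] -= gi
            dense[b, a] -= gi
        rhs = np.zeros(n)
        for i, v in pinned.items():
            dense[i, :] = 0.0
            dense[i, i] = 1.0
            rhs[i] = v
        expected = np.linalg.solve(dense, rhs)
        p = assemble_and_solve(n, edges, g, pinned=pinned)
        assert np.allclose(p, expected, rtol=1e-10)

    def test_singular_component_reported(self):
        with pytest.raises(ValueError, match="singular"):
            assemble_and_solve(4, [(0, 1), (2, 3)], [1e-9, 1e-9],
                               pinned={0: 1.0, 1: 0.5})


def _two_vessel_network():
    nodes = [cf.Node(0, [0, 0, 0], "inlet", "systemic"),
             cf.Node(1, [10, 0, 0], "internal", "systemic"),
             cf.Node(2, [20, 0, 0], "outlet", "L-MCA")]
    vessels = [cf.VesselSpec(0, 0, 1, 1.0, 10.0, 1.6e6),
               cf.VesselSpec(1, 1, 2, 0.8, 10.0, 1.6e6)]
    return cf.VascularNetwork(nodes, vessels)


class TestElasticIteration:
    def test_rigid_limit_single_update(self):
        net = _two_vessel_network()
        for v in net.vessels:
            v.E_Pa = 1e15  # effectively rigid
        model = FlowModel(cf.discretize(net), cf.SolverConfig(relaxation=1.0))
        model.initialize_outlet_resistances()
        its, eps = model.iterate_elastic()
        assert its <= 2
        assert np.allclose(model.r_mm, model.r0_mm, rtol=1e-9)

    def test_converged_state_satisfies_both_laws(self):
        net = _two_vessel_network()
        cfg = cf.SolverConfig()
        model = FlowModel(cf.discretize(net), cfg)
        model.initialize_outlet_resistances()
        model.iterate_elastic()
        # elastic consistency: r(P) residual below 1e-9 * P0
        p_seg = 0.5 * (model.P[model.seg_a] + model.P[model.seg_b])
        r_law = radius_from_pressure(p_seg, cfg.reference_pressure_Pa,
                                     model.r0_mm, model.E_Pa, model.h_mm,
                                     cfg.poisson)
        p_back = cfg.reference_pressure_Pa + \
            (model.r_mm - model.r0_mm) * 1e-3 * model.E_Pa * model.h_mm * 1e-3 \
            / ((model.r0_mm * 1e-3) ** 2 * (1 - cfg.poisson ** 2))
        assert np.allclose(r_law, model.r_mm, rtol=1e-9)
        assert np.max(np.abs(p_back - p_seg)) < 1e-9 * cfg.reference_pressure_Pa
        # mass balance
        assert model.mass_balance_residual() < 1e-8

    @pytest.mark.parametrize("relaxation", [0.4, 1.0])
    def test_fixed_point_independent_of_relaxation_and_start(self, relaxation):
        net = _two_vessel_network()
        cfg = cf.SolverConfig(relaxation=relaxation)
        model = FlowModel(cf.discretize(net), cfg)
        model.initialize_outlet_resistances()
        model.r_mm = model.r0_mm * (1.1 if relaxation < 0.5 else 0.9)
        model.iterate_elastic()
        reference = FlowModel(cf.discretize(net), cf.SolverConfig())
        reference.initialize_outlet_resistances()
        reference.iterate_elastic()
        assert np.allclose(model.P, reference.P, rtol=1e-5)
        assert np.allclose(model.r_mm, reference.r_mm, rtol=1e-6)

    def test_flow_from_conductance_times_dp(self):
        # Q = G dP and velocity uses the mean-radius cross-section
        net = _two_vessel_network()
        model = FlowModel(cf.discretize(net), cf.SolverConfig())
        model.initialize_outlet_resistances()
        model.iterate_elastic()
        g = model.segment_conductances()
        q = model.segment_flows_SI()
        dp = model.P[model.seg_a] - model.P[model.seg_b]
        assert np.allclose(q, g * dp, rtol=1e-14)
        res = model.result()
        v_expected = q / (np.pi * (model.r_mm * 1e-3) ** 2) * 1e3
        assert np.allclose(res.segment_velocities_mm_s, v_expected, rtol=1e-14)


class TestHealthyNetworkProperties:
    def test_global_conservation(self, healthy_small):
        d = healthy_small.result.diagnostics
        assert d["total_outlet_flow_ml_s"] == pytest.approx(100.0, rel=1e-8)
        assert healthy_small.model.mass_balance_residual() < 1e-8

    def test_maximum_principle(self, healthy_small):
        # no interior sources: pressures bounded by inlet and venous values
        p = healthy_small.result.node_pressures_Pa
        p_in = healthy_small.result.inlet_pressure_Pa
        p_out = healthy_small.config.solver.outlet_pressure_Pa
        assert np.all(p <= p_in * (1 + 1e-12))
        assert np.all(p >= p_out * (1 - 1e-12))

    def test_calibration_reaches_both_targets_and_is_unique(self, config_small):
        # starting from doubled outlet resistances must land on the same state
        from dataclasses import replace

        from collateralflow.network import discretize as disc_fn
        net = cf.generate_network(config_small.network)
        disc = disc_fn(net)
        a = FlowModel(disc, config_small.solver)
        a.initialize_outlet_resistances()
        a.calibrate_inlet_boundary()
        b = FlowModel(disc, config_small.solver)
        b.initialize_outlet_resistances()
        b.outlet_R_SI *= 2.0
        b.calibrate_inlet_boundary()
        assert a.inlet_pressure() == pytest.approx(12_500.0, rel=1e-6)
        assert b.inlet_pressure() == pytest.approx(12_500.0, rel=1e-6)
        assert np.allclose(a.outlet_flows_SI(), b.outlet_flows_SI(), rtol=1e-5)
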