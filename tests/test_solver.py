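"""Solver verification on analytic fixtures.

The straight-tube Poiseuille checks compare the developed-region pressure
gradient, centreline velocity and wall shear stress with the closed-form
laminar solution; the bifurcation fixture is checked against the
Hagen-Poiseuille resistance-network oracle in the creeping-flow limit.
"""

import numpy as np
import pytest

from airwaycfd import geometry as G
from airwaycfd import meshing as M
from airwaycfd import postprocess as P
from airwaycfd import solver as S
from airwaycfd.respiration import AIR, FluidProperties, breathing_pattern

from conftest import TUBE_D, TUBE_L, TUBE_U


@pytest.fixture(scope="module")
def tube_solution(poiseuille_solution):
    assert poiseuille_solution.converged
    return poiseuille_solution


def test_tube_pressure_gradient_matches_poiseuille(tube_solution):
    """Developed-region dP/dx tracks 32 mu L U / D^2 at the fixture's
    demonstrated accuracy (regression guard; the printed-precision check
    lives in the acceptance suite)."""
    dp_hp = 32 * AIR.dynamic_viscosity * TUBE_L * TUBE_U / TUBE_D**2
    x1, x2 = 0.45 * TUBE_L, 0.85 * TUBE_L
    pts = np.array([[x1, 0, 0], [x2, 0, 0]])
    p1, p2 = tube_solution.sample_pressure(pts)
    grad_ratio = (p1 - p2) / (x2 - x1) / (dp_hp / TUBE_L)
    assert grad_ratio == pytest.approx(1.0, abs=0.08)


def test_tube_centerline_velocity(tube_solution):
    """Fully developed centreline velocity within 3% of twice the mean."""
    pts = np.array([[0.6 * TUBE_L, 0, 0], [0.8 * TUBE_L, 0, 0]])
    u = tube_solution.sample_velocity(pts)[:, 0]
    assert np.mean(u) == pytest.approx(2 * TUBE_U, rel=0.03)


def test_tube_wall_shear_stress(tube_solution):
    """Developed-region WSS within 5% of 8 mu U / D on average."""
    wall = P.wall_shear_stress(tube_solution)
    mid = np.abs(wall.centroids[:, 0] - 0.65 * TUBE_L) < 0.15 * TUBE_L
    tau = 8 * AIR.dynamic_viscosity * TUBE_U / TUBE_D
    assert wall.wss[mid].mean() == pytest.approx(tau, rel=0.05)


def test_tube_mass_balance(tube_solution):
    assert tube_solution.global_mass_imbalance < 0.005


def test_zero_flow_yields_zero_fields():
    mesh = M.tube_volume_mesh(0.006, 0.002, 0.0005)
    bcs = S.BoundaryConditionSet(
        velocity_inlets=(("inlet", 0.0, np.array([1.0, 0.0, 0.0])),),
        pressure_outlets=(("outlet_1", 0.0),),
        walls=("wall",),
    )
    sol = S.solve_steady(mesh, bcs)
    assert sol.converged
    assert np.all(sol.velocity == 0.0)
    assert np.all(sol.pressure == 0.0)


def test_solver_determinism():
    mesh = M.tube_volume_mesh(0.006, 0.002, 0.0004)
    bcs = S.BoundaryConditionSet(
        velocity_inlets=(("inlet", 0.01, np.array([1.0, 0.0, 0.0])),),
        pressure_outlets=(("outlet_1", 0.0),),
        walls=("wall",),
    )
    settings = S.SolverSettings(max_outer_iterations=60)
    a = S.solve_steady(mesh, bcs, AIR, settings)
    b = S.solve_steady(mesh, bcs, AIR, settings)
    assert np.array_equal(a.velocity, b.velocity)
    assert np.array_equal(a.pressure, b.pressure)


# --------------------------------------------------------------------------
# Resistance-network oracle
# --------------------------------------------------------------------------


def test_network_drop_single_tube():
    tree = G.build_tree_from_levels([(0.01, 0.002, None, None)])
    res = S.poiseuille_network_drop(tree, 1e-6)
    ref = 128 * AIR.dynamic_viscosity * 0.01 * 1e-6 / (np.pi * 0.002**4)
    assert res.root_to_tip_total == pytest.approx(ref)
    assert ref == pytest.approx(0.456, rel=0.01)


def test_network_drop_infant_tree():
    """Root-to-tip total ~6.9 Pa for the infant inspiratory branch flow."""
    from airwaycfd.respiration import branch_flow_rate, phase_flow_rates

    tree = G.build_centerline_tree(G.build_profile("infant"))
    q_insp, _ = phase_flow_rates(breathing_pattern("infant"))
    res = S.poiseuille_network_drop(tree, branch_flow_rate(q_insp, 6))
    per_gen = {}
    for seg in tree.segments:
        per_gen.setdefault(seg.generation_index, res.per_segment_drop[seg.index])
    assert per_gen[6] == pytest.approx(2.33, abs=0.01)
    assert per_gen[7] == pytest.approx(1.47, abs=0.01)
    assert per_gen[8] == pytest.approx(1.73, abs=0.01)
    assert per_gen[9] == pytest.approx(1.35, abs=0.01)
    assert res.root_to_tip_total == pytest.approx(6.89, abs=0.02)


def test_network_drop_linear_in_flow():
    tree = G.build_centerline_tree(G.build_profile("child"))
    a = S.poiseuille_network_drop(tree, 1e-6).root_to_tip_total
    b = S.poiseuille_network_drop(tree, 2e-6).root_to_tip_total
    assert b == pytest.approx(2 * a, rel=1e-12)


# --------------------------------------------------------------------------
# Boundary-condition configuration
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def infant_coarse_mesh(infant_surface):
    return M.generate_volume_mesh(infant_surface, 0.3 * 0.6e-3, n_layers=1, seed=1)


def test_configure_inspiration(infant_coarse_mesh, infant_profile):
    pattern = breathing_pattern("infant")
    bcs = S.configure_phase(infant_coarse_mesh, infant_profile, pattern, "inspiration")
    assert len(bcs.velocity_inlets) == 1
    assert len(bcs.pressure_outlets) == 8
    name, speed, direction = bcs.velocity_inlets[0]
    assert name == "inlet"
    assert speed == pytest.approx(1.16, rel=0.01)
    assert direction @ np.array([1.0, 0, 0]) > 0.99  # into the domain


def test_configure_expiration_flow_split(infant_coarse_mesh, infant_profile):
    """Eight G9 inlets at Q_exp/2^9 inject Q_exp/2^6 in total."""
    pattern = breathing_pattern("infant")
    bcs = S.configure_phase(infant_coarse_mesh, infant_profile, pattern, "expiration")
    assert len(bcs.velocity_inlets) == 8
    assert [n for n, _ in bcs.pressure_outlets] == ["inlet"]
    from airwaycfd.respiration import branch_flow_rate, phase_flow_rates

    _, q_exp = phase_flow_rates(pattern)
    d9 = infant_profile.generation(9).diameter_mm * 1e-3
    total = sum(s * np.pi * d9**2 / 4 for _, s, _ in bcs.velocity_inlets)
    assert total == pytest.approx(branch_flow_rate(q_exp, 6), rel=1e-9)


def test_bc_validation_rejects_incomplete_roles(infant_coarse_mesh):
    bcs = S.BoundaryConditionSet(
        velocity_inlets=(("inlet", 1.0, np.array([1.0, 0, 0])),),
        pressure_outlets=(),
        walls=("wall",),
    )
    with pytest.raises(ValueError):
        bcs.validate(infant_coarse_mesh.patch_names)


def test_settings_validation():
    with pytest.raises(ValueError):
        S.SolverSettings(underrelax_pressure=0.0)
    with pytest.raises(ValueError):
        S.SolverSettings(residual_tolerance=-1.0)
    s = S.SolverSettings()
    assert s.underrelax_pressure == 0.3
    assert s.underrelax_momentum == 0.5
    assert s.residual_tolerance == 1e-5
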