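"""Post-processing on prescribed analytic fields."""

import numpy as np
import pandas as pd
import pytest

from airwaycfd import geometry as G
from airwaycfd import postprocess as P
from airwaycfd import meshing as M

from conftest import make_uniform_solution


@pytest.fixture(scope="module")
def tube_tree_local():
    return G.build_tree_from_levels([(0.01, 0.002, None, None)])


@pytest.fixture(scope="module")
def uniform_solution(coarse_tube_mesh):
    return make_uniform_solution(coarse_tube_mesh, u=(1.0, 0.0, 0.0))


def test_section_stats_uniform_field(uniform_solution, tube_tree_local):
    probes = G.make_probe_set(tube_tree_local, path_generation=0)
    stats = P.section_stats(uniform_solution, probes)
    assert stats.average_velocity[0] == pytest.approx(1.0, rel=1e-6)
    assert stats.center_velocity[0] == pytest.approx(1.0, rel=1e-6)
    assert stats.area[0] == pytest.approx(np.pi * 0.001**2, rel=0.02)
    # flux through the mid section equals area times speed
    assert stats.flux[0] == pytest.approx(stats.area[0], rel=1e-6)


def test_max_velocity_uniform_and_zero(coarse_tube_mesh):
    sol = make_uniform_solution(coarse_tube_mesh, u=(0.0, 0.0, 0.0))
    umax, _ = P.max_velocity(sol)
    assert umax == 0.0
    sol2 = make_uniform_solution(coarse_tube_mesh, u=(3.0, 0.0, 0.0))
    umax2, _ = P.max_velocity(sol2)
    assert umax2 == pytest.approx(3.0)


def test_pressure_drop_zero_flow(coarse_tube_mesh):
    sol = make_uniform_solution(coarse_tube_mesh, u=(0.0, 0.0, 0.0), pressure=0.0)
    assert P.pressure_drop(sol, inlet_patches=["inlet"]) == pytest.approx(0.0)


def test_wall_shear_stress_zero_flow(coarse_tube_mesh):
    sol = make_uniform_solution(coarse_tube_mesh, u=(0.0, 0.0, 0.0))
    wall = P.wall_shear_stress(sol)
    assert np.all(wall.wss >= 0)
    assert wall.max_wss == pytest.approx(0.0, abs=1e-15)


def test_wall_shear_stress_missing_patch(uniform_solution):
    with pytest.raises(ValueError):
        P.wall_shear_stress(uniform_solution, wall_patch="nope")


def test_streamlines_uniform_axial_field(uniform_solution):
    lines = P.trace_streamlines(uniform_solution, n_seeds=40, rng_seed=0)
    assert len(lines.paths) == 40
    done = [e for e in lines.exit_patch if e == "outlet_1"]
    assert len(done) >= 0.9 * 40
    # straight paths: lateral drift well below the tube radius
    for path in lines.paths:
        drift = np.abs(path[:, 1:] - path[0, 1:]).max()
        assert drift < 2e-4


def test_report_rows_and_comparison_columns(coarse_tube_mesh):
    cases = []
    for age, phase, mag in [
        ("infant", "inspiration", 3.0),
        ("child", "inspiration", 2.0),
        ("adult", "inspiration", 1.0),
    ]:
        sol = make_uniform_solution(coarse_tube_mesh, u=(mag, 0.0, 0.0))
        cases.append(P.CaseResult(age=age, phase=phase, solution=sol))
    report = P.build_report(cases)
    assert len(report.table) == 3
    assert "reported_max_velocity" in report.table.columns
    assert report.monotonicity["max_velocity_ms_decreases_with_age_inspiration"]


def test_report_empty_input_rejected():
    with pytest.raises(ValueError):
        P.build_report([])
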