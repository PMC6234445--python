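"""Volume meshing, probe metrics and the mesh-independence machinery."""

import numpy as np
import pytest

from airwaycfd import geometry as G
from airwaycfd import io_vtk
from airwaycfd import meshing as M

from conftest import make_uniform_solution


# --------------------------------------------------------------------------
# Tube meshes
# --------------------------------------------------------------------------


def test_tube_mesh_volume_matches_cylinder(coarse_tube_mesh):
    ref = np.pi * 0.001**2 * 0.01
    assert coarse_tube_mesh.total_volume == pytest.approx(ref, rel=0.02)


def test_tube_mesh_conforming(coarse_tube_mesh):
    mesh = coarse_tube_mesh
    assert 2 * len(mesh.iface_owner) + len(mesh.bface_owner) == 4 * mesh.n_cells
    assert np.all(mesh.cell_volumes > 0)


def test_halving_cell_size_scales_cell_count():
    coarse = M.tube_volume_mesh(0.01, 0.002, 0.0005)
    fine = M.tube_volume_mesh(0.01, 0.002, 0.00025)
    factor = fine.n_cells / coarse.n_cells
    assert 4 <= factor <= 16


def test_wall_layers_form_graded_strata():
    mesh = M.tube_volume_mesh(0.01, 0.002, 0.0004, n_layers=3)
    radii = np.linalg.norm(mesh.points[:, 1:], axis=1)
    near_wall = np.unique(np.round(radii[radii >= 0.5 * 0.001], 9))
    # three graded shells plus the wall ring itself in the outer half
    assert len(near_wall) >= 4
    gaps = np.diff(np.sort(near_wall))
    # strata thin toward the wall
    assert gaps[-1] < gaps[0]


def test_tube_patch_areas(coarse_tube_mesh):
    disk = np.pi * 0.001**2
    assert coarse_tube_mesh.patch_area("inlet") == pytest.approx(disk, rel=0.01)
    assert coarse_tube_mesh.patch_area("outlet_1") == pytest.approx(disk, rel=0.01)


def test_bad_cell_size_rejected():
    with pytest.raises(ValueError):
        M.tube_volume_mesh(0.01, 0.002, -1.0)


# --------------------------------------------------------------------------
# Tree meshes
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def infant_mesh(infant_surface):
    return M.generate_volume_mesh(infant_surface, 0.6e-3 / 4.0, n_layers=1, seed=1)


def test_tree_mesh_volume_matches_surface(infant_surface, infant_mesh):
    assert infant_mesh.total_volume == pytest.approx(
        infant_surface.enclosed_volume, rel=0.02
    )


def test_tree_mesh_patch_areas_match_surface(infant_surface, infant_mesh):
    for name in infant_mesh.patch_names[:-1]:
        assert infant_mesh.patch_area(name) == pytest.approx(
            infant_surface.patch_area(name), rel=0.02
        )
    assert infant_mesh.patch_area("wall") == pytest.approx(
        infant_surface.patch_area("wall"), rel=0.02
    )


def test_tree_mesh_conforming_and_positive(infant_mesh):
    assert 2 * len(infant_mesh.iface_owner) + len(infant_mesh.bface_owner) == (
        4 * infant_mesh.n_cells
    )
    assert np.all(infant_mesh.cell_volumes > 0)
    # all nine caps labelled
    for name in ["inlet"] + [f"outlet_{k}" for k in range(1, 9)]:
        assert len(infant_mesh.patch_faces(name)) > 0


def test_mesh_export_roundtrip(tmp_path, coarse_tube_mesh):
    path = M.export_mesh(coarse_tube_mesh, tmp_path / "tube.msh", "msh")
    pts, cells, bf, bp, names = io_vtk.read_msh(path)
    assert len(pts) == len(coarse_tube_mesh.points)
    assert len(cells) == coarse_tube_mesh.n_cells
    assert names == coarse_tube_mesh.patch_names
    assert np.array_equal(bp, coarse_tube_mesh.bface_patch)
    M.export_mesh(coarse_tube_mesh, tmp_path / "tube.vtu", "vtu")
    assert (tmp_path / "tube.vtu").exists()
    with pytest.raises(ValueError):
        M.export_mesh(coarse_tube_mesh, tmp_path / "tube.xyz", "xyz")


# --------------------------------------------------------------------------
# Probe metric
# --------------------------------------------------------------------------


def test_probe_average_uniform_field_and_linearity(coarse_tube_mesh):
    tree = G.build_tree_from_levels([(0.01, 0.002, None, None)])
    probes = G.make_probe_set(tree, path_generation=0)
    sol = make_uniform_solution(coarse_tube_mesh, u=(1.0, 0.0, 0.0))
    assert M.probe_average_velocity(sol, probes) == pytest.approx(1.0, abs=1e-9)
    sol2 = make_uniform_solution(coarse_tube_mesh, u=(2.0, 0.0, 0.0))
    assert M.probe_average_velocity(sol2, probes) == pytest.approx(
        2.0 * M.probe_average_velocity(sol, probes), rel=1e-9
    )


def test_probe_outside_mesh_rejected(coarse_tube_mesh):
    sol = make_uniform_solution(coarse_tube_mesh)
    with pytest.raises(ValueError):
        sol.sample_velocity(np.array([[0.5, 0.5, 0.5]]))


# --------------------------------------------------------------------------
# Grid convergence index
# --------------------------------------------------------------------------


def test_gci_identical_solutions_is_zero():
    assert M.grid_convergence_index(1.0, 1.0, 2.0, 2.0) == 0.0


def test_gci_formula_value():
    # F_s |(f_c - f_f)/f_f| / (r^p - 1) = 1.25 * 0.01 / 3
    assert M.grid_convergence_index(1.01, 1.00, 2.0, 2.0) == pytest.approx(
        1.25 * 0.01 / 3.0
    )


def test_gci_linear_in_difference():
    a = M.grid_convergence_index(1.03, 1.00, 1.5, 2.0)
    b = M.grid_convergence_index(1.01, 1.00, 1.5, 2.0)
    assert a == pytest.approx(3 * b, rel=1e-9)


def test_gci_invalid_inputs():
    with pytest.raises(ValueError):
        M.grid_convergence_index(1.0, 1.1, 0.9, 2.0)
    with pytest.raises(ValueError):
        M.grid_convergence_index(1.0, 1.1, 2.0, -1.0)
    with pytest.raises(ZeroDivisionError):
        M.grid_convergence_index(1.0, 0.0, 2.0, 2.0)


# --------------------------------------------------------------------------
# Mesh-independence study
# --------------------------------------------------------------------------


def test_study_constant_metric_selects_coarsest(tube_surface):
    probes = G.make_probe_set(tube_surface.tree, path_generation=0)
    res = M.mesh_independence_study(
        tube_surface, [8e-4, 6e-4, 4.5e-4], lambda mesh: 1.0, probes
    )
    assert res.selected_level == 0
    assert res.tolerance_met
    assert all(c == 0.0 for c in res.relative_changes)


def test_study_synthetic_sequence_selects_third_level(tube_surface):
    metrics = iter([1.10, 1.01, 1.005, 1.0049])
    probes = G.make_probe_set(tube_surface.tree, path_generation=0)
    res = M.mesh_independence_study(
        tube_surface,
        [9e-4, 7e-4, 5.5e-4, 4.2e-4],
        lambda mesh: next(metrics),
        probes,
        tolerance=0.003,
    )
    # relative changes: 8.2%, 0.5%, 0.02% -> third level is the first whose
    # change to the next finer one is below 0.3%
    assert res.selected_level == 2
    assert res.tolerance_met


def test_study_vacuous_tolerance_selects_coarsest(tube_surface):
    metrics = iter([2.0, 1.0, 0.5])
    probes = G.make_probe_set(tube_surface.tree, path_generation=0)
    res = M.mesh_independence_study(
        tube_surface, [9e-4, 7e-4, 5e-4], lambda mesh: next(metrics), probes,
        tolerance=1.0,
    )
    assert res.selected_level == 0


def test_study_unmet_tolerance_flags_finest(tube_surface):
    metrics = iter([2.0, 1.0, 0.5])
    probes = G.make_probe_set(tube_surface.tree, path_generation=0)
    res = M.mesh_independence_study(
        tube_surface, [9e-4, 7e-4, 5e-4], lambda mesh: next(metrics), probes,
        tolerance=0.001,
    )
    assert res.selected_level == 2
    assert not res.tolerance_met


def test_study_validates_ladder(tube_surface):
    probes = G.make_probe_set(tube_surface.tree, path_generation=0)
    with pytest.raises(ValueError):
        M.mesh_independence_study(tube_surface, [5e-4], lambda m: 1.0, probes)
    with pytest.raises(ValueError):
        M.mesh_independence_study(
            tube_surface, [5e-4, 6e-4], lambda m: 1.0, probes
        )
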