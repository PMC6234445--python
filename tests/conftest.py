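"""Shared fixtures.

Geometry and meshes are session-scoped: they are deterministic and
read-only for the tests that share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from airwaycfd import geometry, meshing, respiration, solver


@pytest.fixture(scope="session")
def infant_profile():
    return geometry.build_profile("infant")


@pytest.fixture(scope="session")
def infant_tree(infant_profile):
    return geometry.build_centerline_tree(infant_profile)


@pytest.fixture(scope="session")
def infant_surface(infant_profile, infant_tree):
    return geometry.build_surface(infant_tree, infant_profile, resolution=0.12)


@pytest.fixture(scope="session")
def tube_tree():
    # 10 mm long, 2 mm diameter straight tube
    return geometry.build_tree_from_levels([(0.01, 0.002, None, None)])


@pytest.fixture(scope="session")
def tube_surface(tube_tree):
    return geometry.build_surface(tube_tree, resolution=0.1)


@pytest.fixture(scope="session")
def coarse_tube_mesh():
    return meshing.tube_volume_mesh(0.01, 0.002, 0.00035, n_layers=1)


# straight-tube verification fixture: 2 mm bore, 8 mm long, Re ~ 2.7
TUBE_D, TUBE_L, TUBE_U = 0.002, 0.008, 0.02


@pytest.fixture(scope="session")
def poiseuille_solution():
    import numpy as np

    mesh = meshing.tube_volume_mesh(TUBE_L, TUBE_D, 0.0002, n_layers=0)
    bcs = solver.BoundaryConditionSet(
        velocity_inlets=(("inlet", TUBE_U, np.array([1.0, 0.0, 0.0])),),
        pressure_outlets=(("outlet_1", 0.0),),
        walls=("wall",),
    )
    return solver.solve_steady(
        mesh,
        bcs,
        respiration.AIR,
        solver.SolverSettings(max_outer_iterations=700, second_order_blend=1.0),
    )


def make_uniform_solution(mesh, u=(1.0, 0.0, 0.0), pressure=0.0):
    """A FlowSolution carrying a prescribed uniform field (for unit tests)."""
    outlets = tuple(
        (n, 0.0) for n in mesh.patch_names if n.startswith("outlet")
    )
    speed = float(np.linalg.norm(u))
    direction = np.asarray(u, dtype=float) / max(speed, 1e-300)
    # the wall is declared as a Dirichlet-velocity patch carrying the same
    # uniform value, so gradient reconstruction sees a truly uniform field
    bcs = solver.BoundaryConditionSet(
        velocity_inlets=(("inlet", speed, direction), ("wall", speed, direction)),
        pressure_outlets=outlets,
        walls=(),
    )
    geom = solver.FVGeometry(mesh)
    nc = geom.nc
    velocity = np.tile(np.asarray(u, dtype=float), (nc, 1))
    sol = solver.FlowSolution(
        mesh=mesh,
        fluid=respiration.AIR,
        bcs=bcs,
        velocity=velocity,
        pressure=np.full(nc, float(pressure)),
        face_flux=respiration.AIR.density
        * (geom.Sf @ np.asarray(u, dtype=float)),
        bface_flux=respiration.AIR.density
        * (geom.bSf @ np.asarray(u, dtype=float)),
        converged=True,
        final_residuals={},
        iteration_count=0,
    )
    sol._cache["geom"] = geom
    return sol
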