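"""Solver verification against closed-form laminar solutions.

Runs the straight-tube Poiseuille benchmark (developed pressure gradient,
centreline velocity, wall shear stress) and the single-bifurcation
creeping-flow comparison against the Hagen-Poiseuille resistance network.
Writes results/verification.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from airwaycfd import meshing, postprocess, solver, study_pipeline
from airwaycfd.respiration import AIR, FluidProperties

OUT = Path(__file__).resolve().parents[1] / "results"


def tube_benchmark() -> dict:
    fx = study_pipeline.make_fixture(
        "straight_tube", length=0.008, diameter=0.002, flow_rate=6.28e-8
    )
    L, D = fx.params["length"], fx.params["diameter"]
    U = fx.analytic["mean_velocity"]
    mesh = meshing.tube_volume_mesh(L, D, 0.00022, n_layers=2)
    bcs = solver.BoundaryConditionSet(
        velocity_inlets=(("inlet", U, np.array([1.0, 0.0, 0.0])),),
        pressure_outlets=(("outlet_1", 0.0),),
        walls=("wall",),
    )
    sol = solver.solve_steady(
        mesh, bcs, AIR, solver.SolverSettings(max_outer_iterations=700)
    )
    x1, x2 = 0.45 * L, 0.85 * L
    p1, p2 = sol.sample_pressure(np.array([[x1, 0, 0], [x2, 0, 0]]))
    grad = (p1 - p2) / (x2 - x1)
    grad_ref = fx.analytic["poiseuille_drop"] / L
    uc = sol.sample_velocity(np.array([[0.7 * L, 0, 0]]))[0, 0]
    wall = postprocess.wall_shear_stress(sol)
    mid = np.abs(wall.centroids[:, 0] - 0.65 * L) < 0.15 * L
    return {
        "fixture": "straight_tube",
        "cells": mesh.n_cells,
        "converged": sol.converged,
        "pressure_gradient_ratio": grad / grad_ref,
        "centerline_ratio": uc / fx.analytic["centerline_velocity"],
        "wss_ratio": wall.wss[mid].mean() / fx.analytic["wall_shear_stress"],
        "mass_imbalance": sol.global_mass_imbalance,
    }


def bifurcation_benchmark() -> dict:
    """Creeping flow: solver drop must exceed, and stay near, the network oracle."""
    fx = study_pipeline.make_fixture("single_bifurcation", flow_rate=2e-9)
    creeping = FluidProperties(density=1.225, dynamic_viscosity=1.7894e-5)
    mesh = meshing.tree_volume_mesh(fx.tree, 0.13e-3, n_layers=1, seed=1)
    d_parent = 2 * fx.tree.root.radius
    speed = fx.params["flow_rate"] / (np.pi * d_parent**2 / 4)
    bcs = solver.BoundaryConditionSet(
        velocity_inlets=(("inlet", speed, np.array([1.0, 0.0, 0.0])),),
        pressure_outlets=(("outlet_1", 0.0), ("outlet_2", 0.0)),
        walls=("wall",),
    )
    sol = solver.solve_steady(
        mesh, bcs, creeping, solver.SolverSettings(max_outer_iterations=700)
    )
    drop = postprocess.pressure_drop(sol)
    return {
        "fixture": "single_bifurcation",
        "cells": mesh.n_cells,
        "converged": sol.converged,
        "solver_drop_Pa": drop,
        "network_drop_Pa": fx.analytic["network_drop"],
        "drop_ratio": drop / fx.analytic["network_drop"],
        "mass_imbalance": sol.global_mass_imbalance,
    }


def main() -> None:
    rows = [tube_benchmark(), bifurcation_benchmark()]
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "verification.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
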