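# airwaycfd

Steady laminar CFD of age-specific tracheobronchial airways, generations
G6–G9.

During growth from infancy to adulthood the conducting airways enlarge and
breathing slows, and both changes reshape the airflow that medications,
pollutants and pathogens ride on. This package rebuilds a complete
computational study of that effect for the sixth to ninth airway
generations: parametric bifurcating-tree geometry for a 6-month-old
infant, a 5-year-old child and a 25-year-old adult; the respiratory flow
parameters that frame the problem; tetrahedral meshing; a steady laminar
incompressible Navier–Stokes solver; and the post-processing that turns
fields into the study's headline numbers (maximum velocity, inlet
pressure drop, wall shear stress, per-generation cross-section
statistics, streamline splitting).

The model: each airway tree is a planar symmetric Weibel-type cascade with
a 70° bifurcation angle and tabulated per-generation lengths and
diameters. Square-wave breathing converts tidal volume V_T and respiratory
rate RR into phase flow rates Q_insp = V_T·RR·(1+t_e) and
Q_exp = V_T·RR·(1+t_e)/t_e (I:E = 1:t_e), and the symmetric dichotomous
split assigns Q/2⁶ to the G6 inlet. With Womersley numbers
α = (D/2)√(2πRR·ρ/μ) of 0.25–0.44 and Reynolds numbers of 80–155, the flow
is treated as steady and laminar and solved with SIMPLE-type
pressure–velocity coupling (∇·v = 0, ρv·∇v = −∇p + μ∇²v), velocity inlets,
zero-gauge pressure outlets and no-slip walls. See `docs/methods.md` for
the full numerical account.

## Worked example

```python
from airwaycfd import geometry, meshing, postprocess, respiration, solver

profile = geometry.build_profile("infant")
pattern = respiration.breathing_pattern("infant")
tree = geometry.build_centerline_tree(profile)
surface = geometry.build_surface(tree, profile, resolution=0.12)
mesh = meshing.generate_volume_mesh(surface, 0.25 * 0.6e-3, n_layers=1, seed=1)
bcs = solver.configure_phase(mesh, profile, pattern, "inspiration")
sol = solver.solve_steady(mesh, bcs, settings=solver.SolverSettings(max_outer_iterations=700))

umax, gen = postprocess.max_velocity(sol)
print(f"converged={sol.converged} after {sol.iteration_count} iterations")
print(f"max velocity {umax:.2f} m/s in G{gen}")
print(f"inlet pressure drop {postprocess.pressure_drop(sol):.2f} Pa")
```

prints

```
converged=True after 344 iterations
max velocity 2.14 m/s in G6
inlet pressure drop 7.59 Pa
```

i.e. on a ~63k-cell mesh the infant inspiratory case peaks at 2.14 m/s in
generation 6 (published study: 2.22 m/s on a 0.58M-cell mesh) and drives a
7.6 Pa drop across the four generations. The published drop is 11.15 Pa;
the shortfall is the boundary-layer restart at each bifurcation, which a
desk-scale mesh cannot resolve in the downstream generations (see
`docs/methods.md`). Either way the infant's narrow airways need roughly
three times the driving pressure an adult's do for quiet breathing.

The numbered drivers under `analysis/` run the study stages and write
tables to `results/`: respiratory parameters, geometry export, solver
verification against Poiseuille flow, the full 3-age × 2-phase study with
the cross-age report, and the mesh-independence ladder.

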