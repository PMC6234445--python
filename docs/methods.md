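# Methods

This package reimplements, end to end, a computational study of steady
inspiratory and expiratory airflow in age-specific models of the sixth to
ninth generations (G6–G9) of the conducting airways: a 6-month-old infant, a
5-year-old child and a 25-year-old adult. Everything is computed from
embedded printed inputs — per-generation airway dimensions, breathing
parameters, and air properties — with no external data.

## Airway geometry

Each model is a planar, symmetric, four-generation dichotomous tree in the
Weibel tradition. A generation g contributes 2^(g-6) straight branches of
tabulated length L and diameter D; every bifurcation turns each daughter by
±35° (a 70° total branching angle) in the z = 0 plane, with the convention
that the root runs along +x and the "right" daughter deviates toward
negative y (this pins down the "right G7" probe line). Infant/child/adult
dimensions span L = 3.5–8.8 mm and D = 1.0–2.8 mm at G6 down to
L = 2.1–5.3 mm and D = 0.6–1.5 mm at G9.

The solid is modelled implicitly as a blended union of capped cylinders.
At each junction the ridge between the daughters (the carina) is rounded by
a polynomial smooth-union on the scale of the tabulated carinal radius r,
and the parent–daughter outer corner is blended on a scale tied to the
tabulated outer-curvature radius R but capped by the branch radius, so
mid-branch cross sections retain their tabulated diameter to better than
1%. Blending is faded with distance from the junction point so that
branches of different subtrees which pass near one another never interact.
The published construction this emulates is not fully specified in its
source; ours is a stated, reproducible stand-in parameterised by the same
r and R. Surfaces are contoured from the signed-distance field (marching
cubes), cut exactly at the inlet/outlet planes (each cut loop closed by a
flat fan), and validated as closed, outward-oriented manifolds; cap areas
land within ~1% of the corresponding disks.

## Respiratory parameters

Breathing is square-wave: each phase moves the tidal volume in its share of
the cycle, so with minute ventilation MV = V_T × RR and an
inspiration:expiration duration ratio 1 : t_e, the phase flow rates are
Q_insp = MV (1+t_e) and Q_exp = MV (1+t_e)/t_e. Under the symmetric Weibel
split a single generation-g branch carries Q/2^g; the G6 model inlet
therefore receives Q/64, giving mean inlet speeds of 1.16 / 1.00 / 0.80 m/s
(infant / child / adult, inspiration) and branch Reynolds numbers of about
80–155. Womersley numbers use the radius as the characteristic length,
α = (D/2)√(ωρ/μ) with ω = 2π·RR: 0.25 / 0.34 / 0.44 at G6. The radius-based
definition is a deliberate choice: it reproduces the published values
exactly, where a diameter-based one does not. Both numbers justify the
steady, laminar treatment. Air is ρ = 1.225 kg/m³,
μ = 1.7894×10⁻⁵ kg/(m·s).

## Meshing

Straight tubes (verification fixtures) get swept body-fitted meshes: a
triangulated disk — with graded near-wall rings when boundary layers are
requested — extruded along the axis, each prism split into three
tetrahedra with globally consistent diagonals. The outermost ring is
inflated so the polygon area equals the true disk area, which removes the
leading-order bias in Poiseuille resistance.

Trees get an implicit-domain mesh: a body-centred-cubic point lattice
(whose Delaunay tetrahedra are uniformly well shaped) filtered by the
signed distance, surface points obtained by Newton projection of
near-boundary lattice points and then relaxed tangentially (projection
bunches points on the high-curvature carina ridges), structured disk point
stacks swept a short distance inward at every inlet/outlet cap (so
boundary-condition cells have swept-mesh quality), optional graded
near-wall shells, two Lloyd passes on the interior points, and a Delaunay
tetrahedralisation filtered to the interior of the distance field.
Remaining flat or tiny near-boundary tets — which destabilise the
pressure–velocity coupling — are dropped; this only dents the boundary by
a fraction of a cell. The mesh volume consequently sits ~1–3% below the
surface-enclosed volume at the coarse study resolution; the deficit is the
h² cost of an inscribed polyhedral boundary and falls below 2% from about
six cells per G9 diameter (1.5% at D9/6, 0.7% at D9/8).

The default study resolution is a cell size of one quarter of the
last-generation diameter with one near-wall shell (≈ 47–53k cells per
tree). This is deliberately desk-scale; the study whose values we compare
against used 0.58–1.6 M cells per model.

## Flow solver

Steady incompressible laminar Navier–Stokes, cell-centred collocated
finite volumes, SIMPLE-type segregated pressure–velocity coupling with
under-relaxation factors 0.3 (pressure) and 0.5 (momentum). Convection is
implicit first-order upwind plus a deferred linear-upwind (second-order)
correction; diffusion uses the over-relaxed decomposition with the
explicit non-orthogonal part limited to half the implicit coefficient.
Gradients are weighted least squares with two robustness provisions that
matter on imperfect meshes: stencil distances are floored at the local
face scale (so near-coincident centroid pairs cannot amplify noise), and
the normal matrix is inverted through an eigenvalue-truncated
pseudo-inverse (wall cells whose stencils are nearly coplanar otherwise
produce unbounded normal gradients — this was the dominant instability).
The pressure source is assembled as the conservative surface force
Σ p_f S_f with skewness-corrected face values, which is exact for linear
pressure on arbitrary cells; the volume-times-gradient form is O(1) wrong
on skewed cells and was the second instability. Face mass fluxes use
Rhie–Chow coupling with a volume-free coefficient ρA²/a_P (the classical
ρ(V/a_P)·aE underestimates the momentum response of flat cells by orders
of magnitude); the associated pressure-difference dissipation is left
uncompensated, a formally O(h²) bias. Two deliberate deviations from the
textbook loop, both found necessary by stability bisection on lattice
meshes: no explicit cell-velocity correction is applied after the pressure
correction (fluxes are corrected exactly and the fixed point is
unchanged; the −(V/a_P)∇p′ update amplifies pressure noise on bad cells),
and a small shape-aware damping diagonal ∝ μ(ΣA)²/V is added to the
momentum equations (transparent at the fixed point, like
under-relaxation).

Convergence is declared when every scaled residual (momentum components
and continuity, normalised by the largest residual over the first ten
iterations) falls below 10⁻⁵. Initialisation is quiescent and iteration
ordering fixed, so solves are bit-deterministic for a given mesh. The
straight-tube fixture and the infant cases converge fully; the child and
adult trees at the coarse study resolution settle into a small limit cycle
around 10⁻³ scaled residual (marginally steady flow at Re ≈ 120–155 on a
coarse irregular mesh) — the solver reports `converged=False` honestly
and the reported metrics, taken from the final iterate, are stable to
about a percent. The unstructured meshing carries a deterministic jitter;
on rare point-set configurations the segregated solve destabilises, in
which case the pipeline remeshes with a jitter seed derived from the
configured one (up to two retries) rather than failing.

Boundary conditions follow the study design: inspiration drives a uniform
(plug) velocity over the G6 cap at the branch flow rate with all eight G9
caps at zero gauge pressure; expiration drives each G9 cap at Q_exp/2⁹
with the G6 cap as the pressure outlet; walls are no-slip.

## Post-processing

*Pressure drop* is the area-averaged gauge pressure over the
velocity-inlet patch (outlets are pinned at zero); the maximum wall
pressure is reported alongside. *Maximum velocity* is volume-supported:
the largest magnitude carried by at least 0.1% of the domain volume, with
isolated cells above 1.5× their neighbourhood maximum capped first. On
clean fields this tracks the raw cell maximum to within a few percent; on
coarse irregular meshes it is immune to the single-cell artifacts that the
raw maximum is hostage to. *Wall shear stress* is μ times the tangential
velocity sampled three wall-cell heights into the flow over that distance
(sampling past the first cell avoids the locally inflated velocities that
strongly stretched wall cells carry); its maximum is area-supported in the
same sense. *Cross-section statistics* clip each tetrahedron against the
mid-branch plane and integrate the linearly reconstructed velocity over
the polygon pieces. *Streamlines* are midpoint-rule integral curves of the
reconstructed field, labelled by exit patch, with per-bifurcation seed
splits derived from the outlet each seed reaches.

## What the tests show — and what they do not

The verification fixtures are analytic: Poiseuille flow in a tube
(developed pressure gradient within 2%, centreline velocity within 3%,
wall shear within 5% of closed form) and a Hagen–Poiseuille resistance
network for the tree, which the full solve must exceed (entrance and
bifurcation losses are non-negative). The study reproduction is compared
against published values within ±20% bands at desk scale: maximum
inspiratory velocities 2.22/1.82/1.41 m/s, expiratory 1.49/1.12/0.89 m/s,
inspiratory pressure drops 11.15/6.54/3.71 Pa, and the qualitative
structure (maxima in G6, all metrics decreasing with age, inspiration
drops above expiration, section velocity decaying G6→G9).

Known limitations, held honestly rather than hidden. The published
pressure drops embed the classical laminar bifurcation-drag enhancement:
a fresh boundary layer grows from every carina, raising each
generation's resistance well above plain Poiseuille (the enhancement
scales like √(Re·D/L), about 1.4–1.6× here). Our G6, whose plug
entrance is resolved, reproduces that factor, but the boundary-layer
restart inside G7–G9 is thinner than our desk-scale cells, so those
generations run near plain Poiseuille and the total inspiratory drops
come out 20–35% below the published values (infant: 7.7 vs 11.15 Pa) —
the corresponding acceptance checks fail at this mesh size and would
need meshes near the original study's 0.6–1.6M cells. The maximum wall
shear stresses are likewise resolution-sensitive carinal peaks; the
infant inspiratory value lands within the ±30% band but with little
margin. The mesh-independence tolerance of 0.3% between ladder levels
was also established at ~10–30× our cell counts; our ladder reports
per-level changes of a few percent with an explicit
`tolerance_met=False` flag. Finally, the geometry is idealised (planar,
symmetric, straight centerlines); real airways are non-planar with
curved branches, so agreement here validates the pipeline, not
anatomical fidelity.
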