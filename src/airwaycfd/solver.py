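"""Steady incompressible laminar Navier-Stokes on unstructured tet meshes.

Cell-centred collocated finite volumes with SIMPLE pressure-velocity
coupling: implicit first-order upwind convection with a deferred
second-order (linear-upwind) correction, over-relaxed non-orthogonality
treatment of diffusion, weighted least-squares cell gradients, Rhie-Chow
face-flux interpolation, and an under-relaxed pressure-correction
equation.  Under-relaxation defaults are 0.3 (pressure) and 0.5
(momentum); convergence is declared when every scaled residual (momentum
components and continuity, normalised by the largest residual seen over
the first iterations) falls below the residual tolerance, 1e-5 by
default.

Boundary conditions are uniform-velocity inlets, fixed-pressure outlets
and no-slip walls.  Initialisation is quiescent (zero velocity, zero
gauge pressure), iteration ordering is fixed, and no randomisation is
used, so a solve is deterministic for a given mesh and settings.

An analytic Hagen-Poiseuille resistance-network oracle for the
bifurcating tree is provided for verification: the full solver's
pressure drop must exceed it, since entrance and bifurcation losses are
non-negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import LinearOperator, bicgstab, spilu

from .geometry import CenterlineTree
from .meshing import VolumeMesh
from .respiration import (
    AIR,
    BreathingPattern,
    FluidProperties,
    branch_flow_rate,
    mean_inlet_velocity,
    phase_flow_rates,
    reynolds_number,
)

__all__ = [
    "BoundaryConditionSet",
    "SolverSettings",
    "FlowSolution",
    "NetworkDropResult",
    "configure_phase",
    "solve_steady",
    "poiseuille_network_drop",
]

Phase = Literal["inspiration", "expiration"]


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Patch roles: uniform velocity inlets, fixed-pressure outlets, walls."""

    velocity_inlets: tuple[tuple[str, float, np.ndarray], ...]
    pressure_outlets: tuple[tuple[str, float], ...]
    walls: tuple[str, ...]

    def validate(self, patch_names: list[str]) -> None:
        roles: dict[str, str] = {}
        for name, speed, _ in self.velocity_inlets:
            roles[name] = "inlet"
            if speed < 0:
                raise ValueError(f"inlet speed on {name!r} must be non-negative")
        for name, _ in self.pressure_outlets:
            if name in roles:
                raise ValueError(f"patch {name!r} has two roles")
            roles[name] = "outlet"
        for name in self.walls:
            if name in roles:
                raise ValueError(f"patch {name!r} has two roles")
            roles[name] = "wall"
        missing = set(patch_names) - set(roles)
        extra = set(roles) - set(patch_names)
        if missing or extra:
            raise ValueError(
                f"boundary roles do not cover mesh patches exactly "
                f"(missing {sorted(missing)}, unknown {sorted(extra)})"
            )


@dataclass(frozen=True)
class SolverSettings:
    underrelax_pressure: float = 0.3
    underrelax_momentum: float = 0.5
    residual_tolerance: float = 1e-5
    max_outer_iterations: int = 800
    # deferred linear-upwind weight; the 0.75 default keeps the deferred
    # loop stable on irregular lattice meshes (1.0 is fine on swept meshes)
    second_order_blend: float = 0.75
    inner_rtol_momentum: float = 0.05
    inner_rtol_pressure: float = 0.04
    ilu_refresh_interval: int = 20
    # extra momentum diagonal c * mu * (sum of face areas)^2 / V: negligible
    # for well-shaped cells, large for flat (sliver) cells whose velocity
    # would otherwise respond explosively to local pressure noise.  Like
    # under-relaxation it cancels at the fixed point, so the converged
    # solution is unaffected.
    shape_damping: float = 0.1
    verbose: bool = False

    def __post_init__(self) -> None:
        for a in (self.underrelax_pressure, self.underrelax_momentum):
            if not 0 < a <= 1:
                raise ValueError("under-relaxation factors must lie in (0, 1]")
        if self.residual_tolerance <= 0:
            raise ValueError("residual tolerance must be positive")


# --------------------------------------------------------------------------
# Geometry cache
# --------------------------------------------------------------------------


def _limit_correction(T: np.ndarray, implicit_scale: np.ndarray) -> np.ndarray:
    """Scale tangential face vectors so |T| stays below the implicit scale."""
    mag = np.linalg.norm(T, axis=1)
    factor = np.minimum(1.0, implicit_scale / np.maximum(mag, 1e-300))
    return T * factor[:, None]


def _agglomerate_bad_cells(mesh: VolumeMesh) -> np.ndarray:
    """Map each tetrahedron to a control-volume index, merging bad tets.

    Flat (small-inradius) or tiny tets destabilise the pressure-velocity
    coupling; each is merged into the neighbour across its largest internal
    face, forming a polyhedral control volume that face-based finite
    volumes handle without special cases.
    """
    nt = mesh.n_cells
    vols = mesh.cell_volumes
    p = mesh.points[mesh.cells]
    areas = np.zeros(nt)
    from .meshing import _TET_FACES

    for a, b, c in _TET_FACES:
        areas += 0.5 * np.linalg.norm(
            np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]), axis=1
        )
    inradius = 3.0 * vols / np.maximum(areas, 1e-300)
    h = float(np.cbrt(np.median(vols)) * 1.7)  # ~lattice pitch
    bad = (inradius < 0.05 * h) | (vols < 0.02 * h**3)

    fo, fn = mesh.iface_owner, mesh.iface_neigh
    fp = mesh.points[mesh.iface_nodes]
    farea = 0.5 * np.linalg.norm(
        np.cross(fp[:, 1] - fp[:, 0], fp[:, 2] - fp[:, 0]), axis=1
    )
    best_area = np.zeros(nt)
    best_partner = np.arange(nt)
    order = np.argsort(farea)  # ascending; larger faces overwrite
    for idx in order:
        a, b = fo[idx], fn[idx]
        if farea[idx] >= best_area[a]:
            best_area[a] = farea[idx]
            best_partner[a] = b
        if farea[idx] >= best_area[b]:
            best_area[b] = farea[idx]
            best_partner[b] = a

    parent = np.arange(nt)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in np.flatnonzero(bad):
        ri, rj = find(i), find(int(best_partner[i]))
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(nt)])
    _, cell_map = np.unique(roots, return_inverse=True)
    return cell_map


class FVGeometry:
    """Static finite-volume geometric factors for one mesh.

    Badly shaped tets are agglomerated into polyhedral control volumes
    before coefficients are formed; ``tet_to_cell`` maps mesh tets to
    control-volume indices.
    """

    def __init__(self, mesh: VolumeMesh, agglomerate: bool = True):
        self.mesh = mesh
        pts = mesh.points
        if agglomerate:
            self.tet_to_cell = _agglomerate_bad_cells(mesh)
        else:
            self.tet_to_cell = np.arange(mesh.n_cells)
        nc = int(self.tet_to_cell.max()) + 1
        tv = mesh.cell_volumes
        self.V = np.bincount(self.tet_to_cell, tv, minlength=nc)
        C = np.empty((nc, 3))
        for c in range(3):
            C[:, c] = np.bincount(
                self.tet_to_cell, tv * mesh.cell_centroids[:, c], minlength=nc
            ) / self.V
        self.C = C

        f = mesh.iface_nodes
        o_t = self.tet_to_cell[mesh.iface_owner]
        n_t = self.tet_to_cell[mesh.iface_neigh]
        internal = o_t != n_t  # faces inside a merged cell disappear
        self.o = o_t[internal]
        self.n = n_t[internal]
        f = f[internal]
        # tet winding already points owner -> neighbour; a centroid-sign
        # flip would corrupt faces of non-convex agglomerated cells
        self.Sf = 0.5 * np.cross(pts[f[:, 1]] - pts[f[:, 0]], pts[f[:, 2]] - pts[f[:, 0]])
        self.fc = pts[f].mean(axis=1)
        d = self.C[self.n] - self.C[self.o]
        self.area = np.linalg.norm(self.Sf, axis=1)
        self.d = d
        dmag = np.linalg.norm(d, axis=1)
        # over-relaxed decomposition with a skewness guard; thin well-aligned
        # faces (wall layers) legitimately carry large coefficients
        sd = np.einsum("ij,ij->i", self.Sf, d)
        sd = np.maximum(sd, 0.05 * self.area * dmag)
        self.aE = self.area**2 / sd
        self.T = self.Sf - self.aE[:, None] * d
        self._T_scale = self.aE * dmag  # limited once face quality is known
        do = np.linalg.norm(self.fc - self.C[self.o], axis=1)
        dn = np.linalg.norm(self.fc - self.C[self.n], axis=1)
        self.lam = dn / np.maximum(do + dn, 1e-300)  # owner weight
        # skewness vector: face centroid minus the interpolation point on
        # the owner-neighbour line; face values need a gradient correction
        # along it or the pressure force is badly wrong on skewed cells
        self.skew = self.fc - (
            self.lam[:, None] * self.C[self.o]
            + (1 - self.lam)[:, None] * self.C[self.n]
        )

        bf = mesh.bface_nodes
        self.bo = self.tet_to_cell[mesh.bface_owner]
        self.bSf = 0.5 * np.cross(
            pts[bf[:, 1]] - pts[bf[:, 0]], pts[bf[:, 2]] - pts[bf[:, 0]]
        )
        self.bfc = pts[bf].mean(axis=1)
        self.barea = np.linalg.norm(self.bSf, axis=1)
        db = self.bfc - self.C[self.bo]
        self.db = db
        dbmag = np.linalg.norm(db, axis=1)
        sdb = np.einsum("ij,ij->i", self.bSf, db)
        sdb = np.maximum(sdb, 0.05 * self.barea * dbmag)
        self.baE = self.barea**2 / sdb
        self.bT = self.bSf - self.baE[:, None] * db
        self.bT = _limit_correction(self.bT, 0.5 * self.baE * dbmag)
        self.nc = nc

        # floored least-squares distances: weights grow no faster than the
        # local face scale allows, so near-coincident centroid pairs cannot
        # amplify field noise into the gradients
        dfloor = 0.4 * np.sqrt(2.0 * self.area)
        self.ls_dist2 = np.maximum(np.linalg.norm(self.d, axis=1), dfloor) ** 2
        bfloor = 0.4 * np.sqrt(2.0 * self.barea)
        self.ls_bdist2 = np.maximum(np.linalg.norm(self.db, axis=1), bfloor) ** 2

        # per-cell (total face area)^2 / volume: a shape measure that blows
        # up for flat cells, used for stabilising damping
        area_tot = np.bincount(self.o, self.area, minlength=nc)
        area_tot += np.bincount(self.n, self.area, minlength=nc)
        area_tot += np.bincount(self.bo, self.barea, minlength=nc)
        self.cell_area_total = area_tot
        self.cell_area2_over_v = area_tot**2 / np.maximum(self.V, 1e-300)

        # faces touching an agglomerated cell keep first-order convection:
        # linear reconstruction is meaningless on merged irregular cells
        counts = np.bincount(self.tet_to_cell, minlength=nc)
        merged = counts > 1
        self.is_clean = not bool(merged.any())
        self.face_high_order = ~(merged[self.o] | merged[self.n])
        # the explicit non-orthogonality correction must stay below the
        # implicit part on faces of agglomerated cells (the deferred loop
        # diverges there); between well-shaped cells it may be nearly full,
        # which matters for duct-friction accuracy on split-prism faces
        cap = np.where(self.face_high_order, 0.9, 0.5)
        self.T = _limit_correction(self.T, cap * self._T_scale)

        # fixed sparsity for momentum/pressure matrices
        self._rows = np.concatenate([np.arange(nc), self.o, self.n])
        self._cols = np.concatenate([np.arange(nc), self.n, self.o])

    def matrix(self, diag: np.ndarray, a_on: np.ndarray, a_no: np.ndarray) -> csr_matrix:
        data = np.concatenate([diag, a_on, a_no])
        return csr_matrix(
            (data, (self._rows, self._cols)), shape=(self.nc, self.nc)
        )

    def build_ls(self, include_bnd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Weighted least-squares gradient factors.

        ``include_bnd`` marks boundary faces whose (known) face value joins
        the stencil; the rest contribute nothing (zero-gradient).
        Returns (Minv (nc,3,3), w_bnd).
        """
        nc = self.nc
        M = np.zeros((nc, 3, 3))
        w_in = 1.0 / self.ls_dist2
        outer = w_in[:, None, None] * self.d[:, :, None] * self.d[:, None, :]
        for i in range(3):
            for j in range(3):
                np.add.at(M[:, i, j], self.o, outer[:, i, j])
                np.add.at(M[:, i, j], self.n, outer[:, i, j])
        w_b = 1.0 / self.ls_bdist2
        w_b = np.where(include_bnd, w_b, 0.0)
        outer_b = w_b[:, None, None] * self.db[:, :, None] * self.db[:, None, :]
        for i in range(3):
            for j in range(3):
                np.add.at(M[:, i, j], self.bo, outer_b[:, i, j])
        # eigenvalue-floored pseudo-inverse: a wall cell whose stencil
        # directions are nearly coplanar (boundary faces excluded) would
        # otherwise produce unbounded gradients along the missing direction
        vals, vecs = np.linalg.eigh(M)
        cut = 0.1 * np.maximum(vals[:, -1], 1e-300)
        inv_vals = np.where(vals > cut[:, None], 1.0 / np.maximum(vals, 1e-300), 0.0)
        Minv = np.einsum("nik,nk,njk->nij", vecs, inv_vals, vecs)
        return Minv, w_b

    def pressure_face_force(
        self,
        phi: np.ndarray,
        outlet_mask: np.ndarray,
        phi_outlet: np.ndarray,
        grad: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-cell surface pressure force sum(p_f S_f), outward convention.

        Volume does not appear, so the result stays bounded on sliver
        cells (unlike V times a reconstructed gradient).
        """
        lam = self.lam
        o, n, bo = self.o, self.n, self.bo
        phi_f = lam * phi[o] + (1 - lam) * phi[n]
        if grad is None:
            phi_b_ex = phi[bo]
        else:
            g_f = lam[:, None] * grad[o] + (1 - lam)[:, None] * grad[n]
            phi_f = phi_f + np.einsum("nc,nc->n", g_f, self.skew)
            phi_b_ex = phi[bo] + np.einsum("nc,nc->n", grad[bo], self.db)
        phi_b = np.where(outlet_mask, phi_outlet, phi_b_ex)
        force = np.zeros((self.nc, 3))
        for c in range(3):
            force[:, c] = (
                np.bincount(o, phi_f * self.Sf[:, c], minlength=self.nc)
                - np.bincount(n, phi_f * self.Sf[:, c], minlength=self.nc)
                + np.bincount(bo, phi_b * self.bSf[:, c], minlength=self.nc)
            )
        return force

    def ls_grad(
        self,
        phi: np.ndarray,
        Minv: np.ndarray,
        w_b: np.ndarray,
        phi_b: np.ndarray | None,
    ) -> np.ndarray:
        """Gradient of a cell field (phi may be (nc,) or (nc, k))."""
        scalar = phi.ndim == 1
        if scalar:
            phi = phi[:, None]
        k = phi.shape[1]
        w_in = 1.0 / self.ls_dist2
        rhs = np.zeros((self.nc, 3, k))
        dphi = phi[self.n] - phi[self.o]
        for c in range(3):
            # dx and dphi both flip sign from the neighbour's viewpoint, so
            # owner and neighbour receive the same contribution
            contrib = (w_in * self.d[:, c])[:, None] * dphi
            for m in range(k):
                rhs[:, c, m] += np.bincount(self.o, contrib[:, m], minlength=self.nc)
                rhs[:, c, m] += np.bincount(self.n, contrib[:, m], minlength=self.nc)
        if phi_b is not None:
            if phi_b.ndim == 1:
                phi_b = phi_b[:, None]
            dphib = phi_b - phi[self.bo]
            for c in range(3):
                contrib = (w_b * self.db[:, c])[:, None] * dphib
                for m in range(k):
                    rhs[:, c, m] += np.bincount(self.bo, contrib[:, m], minlength=self.nc)
        g = np.einsum("nij,njk->nik", Minv, rhs)
        return g[:, :, 0] if scalar else g


# --------------------------------------------------------------------------
# Boundary configuration
# --------------------------------------------------------------------------


def configure_phase(
    mesh: VolumeMesh,
    profile,
    pattern: BreathingPattern,
    phase: Phase,
    fluid: FluidProperties = AIR,
) -> BoundaryConditionSet:
    """Boundary conditions for one breathing phase on a G6-G9 tree mesh.

    Inspiration: the G6 cap is a uniform velocity inlet carrying the
    whole-lung inspiratory flow split to one generation-6 branch
    (Q/2**6); the eight G9 caps are zero-gauge-pressure outlets.
    Expiration: each G9 cap injects Q_exp/2**9 and the G6 cap is the
    pressure outlet.  Walls are no-slip.
    """
    q_insp, q_exp = phase_flow_rates(pattern)
    g_in = profile.dims[0].generation_index
    g_out = profile.dims[-1].generation_index
    d_in = profile.dims[0].diameter_mm * 1e-3
    d_out = profile.dims[-1].diameter_mm * 1e-3
    outlet_names = [n for n in mesh.patch_names if n.startswith("outlet")]
    if "inlet" not in mesh.patch_names or not outlet_names:
        raise ValueError("mesh is missing inlet/outlet patch labels")

    def inward_normal(name: str) -> np.ndarray:
        geom_faces = mesh.patch_faces(name)
        av = mesh.boundary_face_area_vectors()[geom_faces]
        n = av.sum(axis=0)
        return -n / np.linalg.norm(n)

    if phase == "inspiration":
        speed = mean_inlet_velocity(branch_flow_rate(q_insp, g_in), d_in)
        bcs = BoundaryConditionSet(
            velocity_inlets=(("inlet", speed, inward_normal("inlet")),),
            pressure_outlets=tuple((n, 0.0) for n in outlet_names),
            walls=("wall",),
        )
        re = reynolds_number(speed, d_in, fluid)
    elif phase == "expiration":
        speed = mean_inlet_velocity(branch_flow_rate(q_exp, g_out), d_out)
        bcs = BoundaryConditionSet(
            velocity_inlets=tuple(
                (n, speed, inward_normal(n)) for n in outlet_names
            ),
            pressure_outlets=(("inlet", 0.0),),
            walls=("wall",),
        )
        re = reynolds_number(
            mean_inlet_velocity(branch_flow_rate(q_exp, g_in), d_in), d_in, fluid
        )
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if re > 2000:
        warnings.warn(
            f"branch Reynolds number {re:.0f} exceeds 2000; laminar model "
            "assumption is questionable",
            stacklevel=2,
        )
    bcs.validate(mesh.patch_names)
    return bcs


# --------------------------------------------------------------------------
# Solution container
# --------------------------------------------------------------------------


@dataclass
class FlowSolution:
    mesh: VolumeMesh
    fluid: FluidProperties
    bcs: BoundaryConditionSet
    velocity: np.ndarray  # (nc, 3)
    pressure: np.ndarray  # (nc,)
    face_flux: np.ndarray  # internal mass fluxes, owner -> neighbour (kg/s)
    bface_flux: np.ndarray  # boundary mass fluxes, outward (kg/s)
    converged: bool
    final_residuals: dict[str, float]
    iteration_count: int
    residual_history: list[dict[str, float]] = field(default_factory=list)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def geometry(self) -> FVGeometry:
        if "geom" not in self._cache:
            self._cache["geom"] = FVGeometry(self.mesh)
        return self._cache["geom"]

    def _interp_setup(self):
        if "kdtree" not in self._cache:
            from scipy.spatial import cKDTree

            geom = self.geometry
            bc_role, bc_u, bc_p = _boundary_arrays(self.mesh, self.bcs)
            Minv, w_b = geom.build_ls(include_bnd=bc_role != 1)
            grad_u = geom.ls_grad(self.velocity, Minv, w_b, bc_u)
            self._cache["kdtree"] = cKDTree(geom.C)
            self._cache["grad_u"] = grad_u
            Minv_p, w_bp = geom.build_ls(include_bnd=bc_role == 1)
            self._cache["grad_p"] = geom.ls_grad(self.pressure, Minv_p, w_bp, bc_p)
        return self._cache["kdtree"]

    def locate_cells(self, points: np.ndarray) -> np.ndarray:
        tree = self._interp_setup()
        _, idx = tree.query(np.atleast_2d(points))
        return idx

    def sample_velocity(self, points: np.ndarray) -> np.ndarray:
        """Linear (gradient-reconstructed) velocity at arbitrary points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.locate_cells(pts)
        geom = self.geometry
        dist = np.linalg.norm(pts - geom.C[idx], axis=1)
        hloc = np.cbrt(geom.V[idx]) * 3.0
        if np.any(dist > hloc):
            raise ValueError("sample point lies outside the mesh")
        g = self._cache["grad_u"]
        dx = pts - geom.C[idx]
        return self.velocity[idx] + np.einsum("nci,nc->ni", g[idx], dx)

    def sample_pressure(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.locate_cells(pts)
        geom = self.geometry
        dx = pts - geom.C[idx]
        g = self._cache["grad_p"]
        return self.pressure[idx] + np.einsum("nc,nc->n", g[idx], dx)

    def velocity_gradients(self) -> np.ndarray:
        self._interp_setup()
        return self._cache["grad_u"]

    def pressure_gradients(self) -> np.ndarray:
        self._interp_setup()
        return self._cache["grad_p"]

    @property
    def global_mass_imbalance(self) -> float:
        """|sum inflow - sum outflow| / sum inflow over the boundary."""
        inflow = -self.bface_flux[self.bface_flux < 0].sum()
        net = self.bface_flux.sum()
        if inflow == 0:
            return 0.0
        return abs(net) / inflow


def _boundary_arrays(mesh: VolumeMesh, bcs: BoundaryConditionSet):
    """Per-boundary-face role (0 inlet/Dirichlet-u, 1 outlet, 2 wall) and values."""
    nb = len(mesh.bface_owner)
    role = np.full(nb, 2, dtype=int)
    bc_u = np.zeros((nb, 3))
    bc_p = np.zeros(nb)
    for name, speed, direction in bcs.velocity_inlets:
        faces = mesh.patch_faces(name)
        role[faces] = 0
        bc_u[faces] = speed * np.asarray(direction)
    for name, p0 in bcs.pressure_outlets:
        faces = mesh.patch_faces(name)
        role[faces] = 1
        bc_p[faces] = p0
    for name in bcs.walls:
        role[mesh.patch_faces(name)] = 2
    return role, bc_u, bc_p


# --------------------------------------------------------------------------
# SIMPLE solver
# --------------------------------------------------------------------------


def solve_steady(
    mesh: VolumeMesh,
    bcs: BoundaryConditionSet,
    fluid: FluidProperties = AIR,
    settings: SolverSettings | None = None,
) -> FlowSolution:
    """SIMPLE iteration to a steady laminar solution.

    Never raises on stagnation: a non-converged result is returned with
    ``converged=False`` and the residual history attached.
    """
    settings = settings or SolverSettings()
    bcs.validate(mesh.patch_names)
    geom = FVGeometry(mesh)
    rho, mu = fluid.density, fluid.dynamic_viscosity
    nc = geom.nc
    o, n = geom.o, geom.n
    lam = geom.lam[:, None]

    bc_role, bc_u, bc_p = _boundary_arrays(mesh, bcs)
    is_dirichlet = bc_role != 1  # inlets and walls fix the velocity
    is_outlet = bc_role == 1

    Minv_u, w_bu = geom.build_ls(include_bnd=is_dirichlet)
    Minv_p, w_bp = geom.build_ls(include_bnd=is_outlet)

    u = np.zeros((nc, 3))
    p = np.zeros(nc)
    # fixed boundary mass fluxes on Dirichlet faces
    bmdot_fixed = rho * np.einsum("ij,ij->i", bc_u, geom.bSf)
    bmdot = np.where(is_dirichlet, bmdot_fixed, 0.0)
    mdot = np.zeros(len(o))

    alpha_u = settings.underrelax_momentum
    alpha_p = settings.underrelax_pressure
    beta = settings.second_order_blend

    hist: list[dict[str, float]] = []
    norms: dict[str, float] = {}
    converged = False
    diverged = False
    ilu = None
    it = 0

    total_inlet_flux = float(np.abs(bmdot_fixed[bc_role == 0]).sum())
    if total_inlet_flux == 0.0:
        # no-flow configuration: the quiescent state is the exact solution
        return FlowSolution(
            mesh, fluid, bcs, u, p, mdot, bmdot, True,
            {"u": 0.0, "v": 0.0, "w": 0.0, "continuity": 0.0}, 0, [],
        )

    out_mask = is_outlet
    for it in range(1, settings.max_outer_iterations + 1):
        grad_p = geom.ls_grad(p, Minv_p, w_bp, bc_p)
        grad_u = geom.ls_grad(u, Minv_u, w_bu, bc_u)  # (nc, 3, 3): d u_k / d x_c

        # ---- momentum matrix (shared by the three components)
        diag = np.zeros(nc)
        a_on = np.zeros(len(o))
        a_no = np.zeros(len(o))
        b = np.zeros((nc, 3))

        pos = np.maximum(mdot, 0.0)
        neg = np.minimum(mdot, 0.0)
        diag += np.bincount(o, pos, minlength=nc)
        diag += np.bincount(n, -neg, minlength=nc)
        a_on += neg
        a_no += -pos

        gdiff = mu * geom.aE
        diag += np.bincount(o, gdiff, minlength=nc)
        diag += np.bincount(n, gdiff, minlength=nc)
        a_on -= gdiff
        a_no -= gdiff

        # deferred second-order convection + non-orthogonal diffusion
        up = np.where(mdot >= 0.0, o, n)
        d_up = geom.fc - geom.C[up]
        u_face_ho = np.einsum("nck,nc->nk", grad_u[up], d_up)
        # limit the reconstruction by the face difference so the deferred
        # loop stays bounded on irregular stencils
        bound = np.abs(u[n] - u[o])
        u_face_ho = np.clip(u_face_ho, -bound, bound)
        corr = (beta * mdot * geom.face_high_order)[:, None] * u_face_ho
        gf = lam[:, :, None] * grad_u[o] + (1 - lam)[:, :, None] * grad_u[n]
        dnon = mu * np.einsum("nck,nc->nk", gf, geom.T)
        for k in range(3):
            b[:, k] -= np.bincount(o, corr[:, k], minlength=nc)
            b[:, k] += np.bincount(n, corr[:, k], minlength=nc)
            b[:, k] += np.bincount(o, dnon[:, k], minlength=nc)
            b[:, k] -= np.bincount(n, dnon[:, k], minlength=nc)

        # boundary faces
        gb = mu * geom.baE
        # Dirichlet velocity (inlets, walls): implicit diffusion + known flux
        dir_idx = np.flatnonzero(is_dirichlet)
        diag += np.bincount(geom.bo[dir_idx], gb[dir_idx], minlength=nc)
        inflow = np.minimum(bmdot[dir_idx], 0.0)
        for k in range(3):
            b[:, k] += np.bincount(
                geom.bo[dir_idx],
                gb[dir_idx] * bc_u[dir_idx, k] - inflow * bc_u[dir_idx, k],
                minlength=nc,
            )
            # explicit non-orthogonal boundary diffusion
            gbT = mu * np.einsum(
                "nc,nc->n", grad_u[geom.bo[dir_idx], :, k], geom.bT[dir_idx]
            )
            b[:, k] += np.bincount(geom.bo[dir_idx], gbT, minlength=nc)
        diag += np.bincount(
            geom.bo[dir_idx], np.maximum(bmdot[dir_idx], 0.0), minlength=nc
        )
        # outlets: pure convective outflow, zero-gradient diffusion; momentary
        # backflow is dropped from the diagonal to keep it positive
        out_idx = np.flatnonzero(is_outlet)
        diag += np.bincount(
            geom.bo[out_idx], np.maximum(bmdot[out_idx], 0.0), minlength=nc
        )

        # pressure source as the surface force sum(p_f S_f): bounded on
        # sliver cells, exact for constant pressure
        b -= geom.pressure_face_force(p, out_mask, bc_p, grad=grad_p)

        # residual of the un-relaxed equations at the current state
        A0 = geom.matrix(diag, a_on, a_no)
        res_vec = b - A0 @ u
        res = np.abs(res_vec).sum(axis=0)

        # implicit under-relaxation plus shape-aware damping
        diag_r = diag / alpha_u + settings.shape_damping * mu * geom.cell_area2_over_v
        b += (diag_r - diag)[:, None] * u
        A = geom.matrix(diag_r, a_on, a_no)

        # delta form keeps the inner tolerance meaningful: the correction is
        # solved from zero against the true momentum residual
        Mprec = LinearOperator((nc, nc), matvec=lambda x: x / diag_r)
        res_rel = b - A @ u
        for k in range(3):
            du, _ = bicgstab(
                A, res_rel[:, k], M=Mprec,
                rtol=settings.inner_rtol_momentum, atol=0.0, maxiter=80,
            )
            u[:, k] = u[:, k] + du

        # ---- Rhie-Chow face fluxes
        u_f = lam * u[o] + (1 - lam) * u[n]
        # pressure-velocity coupling coefficient: rho A^2 / aP matches the
        # flux response of the momentum equation to a face pressure jump
        # even on sliver cells, where the classical (V/aP) aE form
        # underestimates it by orders of magnitude and diverges
        aPf = geom.lam * diag_r[o] + (1 - geom.lam) * diag_r[n]
        Df = 0.5 * rho * geom.area**2 / aPf
        # the plain pressure-difference dissipation is kept uncompensated:
        # reconstructed-gradient compensation re-excites the unstable modes
        # of badly shaped cells, and the residual bias is O(h^2)
        mdot = rho * np.einsum("ij,ij->i", u_f, geom.Sf) - Df * (p[n] - p[o])
        Db = 0.5 * rho * geom.barea**2 / diag_r[geom.bo]
        m_out = rho * np.einsum("ij,ij->i", u[geom.bo], geom.bSf) - Db * (
            (bc_p - p[geom.bo]) - np.einsum("ij,ij->i", grad_p[geom.bo], geom.db)
        )
        bmdot = np.where(is_dirichlet, bmdot_fixed, m_out)

        # ---- pressure correction
        imb = (
            np.bincount(o, mdot, minlength=nc)
            - np.bincount(n, mdot, minlength=nc)
            + np.bincount(geom.bo, bmdot, minlength=nc)
        )
        res_c = float(np.abs(imb).sum())

        diag_p = np.bincount(o, Df, minlength=nc) + np.bincount(n, Df, minlength=nc)
        diag_p += np.bincount(geom.bo[out_idx], Db[out_idx], minlength=nc)
        Ap = geom.matrix(diag_p, -Df, -Df)

        if ilu is None or (it % settings.ilu_refresh_interval) == 0:
            try:
                ilu = spilu(Ap.tocsc(), drop_tol=1e-5, fill_factor=12.0)
            except RuntimeError:
                ilu = None
        Mp = (
            LinearOperator((nc, nc), matvec=ilu.solve) if ilu is not None else None
        )
        pc, _ = bicgstab(
            Ap, -imb, M=Mp, rtol=settings.inner_rtol_pressure, atol=0.0, maxiter=400
        )

        # The explicit cell-velocity correction is applied only on clean
        # meshes (no agglomerated cells): there it completes the classic
        # SIMPLE update and recovers second-order duct accuracy.  On
        # irregular meshes the -(V/aP) grad p' update amplifies pressure
        # noise from badly shaped cells into a runaway, and since the face
        # fluxes are corrected exactly either way, the fixed point does
        # not depend on this step.
        if geom.is_clean:
            zeros_b = np.zeros(len(bc_p))
            grad_pc = geom.ls_grad(pc, Minv_p, w_bp, zeros_b)
            pc_force = geom.pressure_face_force(pc, out_mask, zeros_b, grad=grad_pc)
            # the 0.5 matches the coupling coefficient Df, so the cell
            # update and the face-flux update stay flux-consistent
            u -= 0.5 * pc_force / np.maximum(diag_r, 1e-300)[:, None]
        p += alpha_p * pc
        mdot += Df * (pc[o] - pc[n])
        bmdot = bmdot + np.where(is_outlet, Db * pc[geom.bo], 0.0)

        if settings.verbose:
            umag = np.linalg.norm(u, axis=1)
            iu = int(np.argmax(umag))
            ip = int(np.argmax(np.abs(pc)))
            print(
                f"  [{it}] max|u| {umag[iu]:.3e} cell {iu} {np.round(geom.C[iu]*1e3,2)}"
                f" | max|pc| {np.abs(pc[ip]):.3e} cell {ip} {np.round(geom.C[ip]*1e3,2)}"
                f" | res {res[0]:.2e} cont {res_c:.2e}",
                flush=True,
            )

        # ---- residual bookkeeping (scaled by the early-iteration maximum)
        raw = {"u": res[0], "v": res[1], "w": res[2], "continuity": res_c}
        for key, val in raw.items():
            if it <= 10:
                norms[key] = max(norms.get(key, 1e-300), val)
        scaled = {k: raw[k] / norms[k] for k in raw}
        hist.append(scaled)
        if not all(math.isfinite(v) for v in raw.values()) or any(
            v > 1e6 for v in scaled.values()
        ):
            diverged = True
            break
        if it > 10 and all(v < settings.residual_tolerance for v in scaled.values()):
            converged = True
            break

    return FlowSolution(
        mesh=mesh,
        fluid=fluid,
        bcs=bcs,
        velocity=u,
        pressure=p,
        face_flux=mdot,
        bface_flux=bmdot,
        converged=converged and not diverged,
        final_residuals=hist[-1] if hist else {},
        iteration_count=it,
        residual_history=hist,
    )


# --------------------------------------------------------------------------
# Analytic resistance-network oracle
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkDropResult:
    per_segment_drop: dict[int, float]  # Pa, by segment index
    root_to_tip_total: float  # Pa


def poiseuille_network_drop(
    tree: CenterlineTree, q_root: float, fluid: FluidProperties = AIR
) -> NetworkDropResult:
    """Hagen-Poiseuille drop of the symmetric tree, flow halving per split.

    ``q_root`` is the volumetric flow (m^3/s) entering the tree's root
    branch.  Per segment dP = 128 mu L Q / (pi D^4); the root-to-tip total
    follows any path by symmetry.
    """
    mu = fluid.dynamic_viscosity
    drops: dict[int, float] = {}

    def walk(idx: int, q: float) -> None:
        seg = tree.segments[idx]
        d = 2.0 * seg.radius
        if d <= 0:
            raise ValueError("zero-diameter segment")
        drops[idx] = 128.0 * mu * seg.length * q / (math.pi * d**4)
        for child in seg.children:
            walk(child, q / 2.0)

    walk(tree.root.index, q_root)
    total = 0.0
    idx = tree.root.index
    while True:
        total += drops[idx]
        children = tree.segments[idx].children
        if not children:
            break
        idx = children[0]
    return NetworkDropResult(drops, total)
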