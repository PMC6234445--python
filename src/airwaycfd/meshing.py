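"""Tetrahedral volume meshing of airway surfaces, and mesh-independence tools.

Two mesh constructions are provided behind :func:`generate_volume_mesh`:

* straight single tubes get a body-fitted swept mesh (a triangulated disk,
  optionally with graded near-wall rings, extruded along the axis and each
  prism split into three tetrahedra), which resolves Poiseuille flow
  accurately;
* bifurcating trees get a lattice mesh fitted to the implicit solid: jittered
  cubic lattice points inside the signed-distance field, surface points
  obtained by Newton projection of near-boundary lattice points, structured
  disk point sets on every inlet/outlet cap, optional graded near-wall point
  shells, and a Delaunay tetrahedralisation filtered to the interior.

Mesh independence follows the usual grid-convergence-index practice: a ladder
of decreasing cell sizes, a scalar probe metric per level, and selection of
the coarsest level whose relative change to the next finer one is below
tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

from .geometry import (
    AirwaySurface,
    CenterlineTree,
    ProbeSet,
    cap_specs,
    project_to_surface,
    signed_distance_gradient,
    tree_signed_distance,
)

__all__ = [
    "VolumeMesh",
    "MeshStudyResult",
    "MeshingError",
    "generate_volume_mesh",
    "tube_volume_mesh",
    "tree_volume_mesh",
    "probe_average_velocity",
    "grid_convergence_index",
    "mesh_independence_study",
    "export_mesh",
]

# tet faces opposite each vertex, wound outward for a positively oriented tet
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


class MeshingError(RuntimeError):
    pass


@dataclass
class VolumeMesh:
    """Conforming tetrahedral mesh with labelled boundary facets."""

    points: np.ndarray  # (nv, 3) m
    cells: np.ndarray  # (nt, 4) int, positively oriented
    iface_nodes: np.ndarray  # (nf, 3) internal faces
    iface_owner: np.ndarray
    iface_neigh: np.ndarray
    bface_nodes: np.ndarray  # (nb, 3) boundary faces, wound outward
    bface_owner: np.ndarray
    bface_patch: np.ndarray  # (nb,) index into patch_names
    patch_names: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_volumes(self) -> np.ndarray:
        if "_volumes" not in self.metadata:
            self.metadata["_volumes"] = _tet_volumes(self.points, self.cells)
        return self.metadata["_volumes"]

    @property
    def cell_centroids(self) -> np.ndarray:
        if "_centroids" not in self.metadata:
            self.metadata["_centroids"] = self.points[self.cells].mean(axis=1)
        return self.metadata["_centroids"]

    @property
    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())

    def boundary_face_area_vectors(self) -> np.ndarray:
        p = self.points
        f = self.bface_nodes
        return 0.5 * np.cross(p[f[:, 1]] - p[f[:, 0]], p[f[:, 2]] - p[f[:, 0]])

    def patch_area(self, name: str) -> float:
        idx = self.patch_names.index(name)
        areas = np.linalg.norm(self.boundary_face_area_vectors(), axis=1)
        return float(areas[self.bface_patch == idx].sum())

    def patch_faces(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.bface_patch == self.patch_names.index(name))

    def quality(self) -> dict[str, float]:
        """Radius-ratio style quality summary (longest edge over inradius)."""
        p = self.points[self.cells]
        vol = self.cell_volumes
        e = np.stack(
            [
                p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0],
                p[:, 2] - p[:, 1], p[:, 3] - p[:, 1], p[:, 3] - p[:, 2],
            ],
            axis=1,
        )
        lmax = np.linalg.norm(e, axis=2).max(axis=1)
        areas = np.zeros(len(vol))
        for a, b, c in _TET_FACES:
            areas += 0.5 * np.linalg.norm(
                np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]), axis=1
            )
        inradius = 3.0 * vol / areas
        ratio = lmax / np.maximum(inradius, 1e-300)
        return {
            "worst_edge_to_inradius": float(ratio.max()),
            "median_edge_to_inradius": float(np.median(ratio)),
            "min_volume": float(vol.min()),
        }


def _tet_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    p = points[cells]
    return (
        np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        / 6.0
    )


def _orient_positive(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    vol = _tet_volumes(points, cells)
    cells = cells.copy()
    neg = vol < 0
    cells[neg] = cells[neg][:, [1, 0, 2, 3]]
    return cells


def _extract_faces(cells: np.ndarray):
    """Internal and boundary faces of a positively oriented tet mesh."""
    nt = len(cells)
    faces = cells[:, _TET_FACES].reshape(-1, 3)  # (4 nt, 3) outward wound
    owner = np.repeat(np.arange(nt), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    ks = key[order]
    same = np.all(ks[1:] == ks[:-1], axis=1)
    first_of_pair = np.flatnonzero(same)
    paired = np.zeros(len(ks), dtype=bool)
    paired[first_of_pair] = True
    paired[first_of_pair + 1] = True
    int_a = order[first_of_pair]
    int_b = order[first_of_pair + 1]
    bnd = order[~paired]
    return faces[int_a], owner[int_a], owner[int_b], faces[bnd], owner[bnd]


def _connected_filter(cells: np.ndarray) -> np.ndarray:
    """Boolean mask keeping the largest face-connected cell component."""
    _, o, n, _, _ = _extract_faces(cells)
    nt = len(cells)
    g = coo_matrix((np.ones(len(o)), (o, n)), shape=(nt, nt))
    ncomp, labels = connected_components(g, directed=False)
    if ncomp == 1:
        return np.ones(nt, dtype=bool)
    counts = np.bincount(labels)
    return labels == np.argmax(counts)


# --------------------------------------------------------------------------
# Disk points (shared by the tube cross-section and cap patches)
# --------------------------------------------------------------------------


def _disk_points(radius: float, spacing: float, n_layers: int = 0) -> np.ndarray:
    """2D point set covering a disk, with optional graded near-wall rings.

    The outermost ring is inflated slightly so its polygon area equals the
    true disk area.
    """
    thicknesses: list[float] = []
    if n_layers > 0:
        t = 0.35 * spacing
        for _ in range(n_layers):
            thicknesses.append(t)
            t *= 1.5
        total = sum(thicknesses)
        cap = 0.45 * radius
        if total > cap:
            scale = cap / total
            thicknesses = [t * scale for t in thicknesses]
    band = sum(thicknesses)
    inner = radius - band
    n_core = max(1, int(round(inner / spacing)))
    radii = list(np.linspace(0.0, inner, n_core + 1))
    acc = inner
    for t in reversed(thicknesses):  # thinnest ring right at the wall
        acc += t
        radii.append(acc)
    pts = [np.zeros((1, 2))]
    for j, r in enumerate(radii[1:], start=1):
        n_theta = max(6, int(round(2 * math.pi * r / spacing)))
        rr = r
        if j == len(radii) - 1:  # polygon-area correction at the rim
            rr = radius * math.sqrt(
                2 * math.pi / (n_theta * math.sin(2 * math.pi / n_theta))
            )
        theta = (np.arange(n_theta) + 0.5 * (j % 2)) * 2 * math.pi / n_theta
        pts.append(np.stack([rr * np.cos(theta), rr * np.sin(theta)], axis=1))
    return np.vstack(pts)


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction
    e1 = np.array([0.0, 1.0, 0.0]) if abs(d[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ d) * d
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


# --------------------------------------------------------------------------
# Swept tube mesh
# --------------------------------------------------------------------------


def _split_prisms(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split prisms (bottom tri, top tri) into 3 conforming tets each.

    Quad-face diagonals run through the smallest global bottom index, which
    is consistent across neighbouring prisms in a layered extrusion.
    """
    rot = np.argmin(bottom, axis=1)
    idx = (np.arange(3)[None, :] + rot[:, None]) % 3
    b = np.take_along_axis(bottom, idx, axis=1)
    t = np.take_along_axis(top, idx, axis=1)
    a, b1, c = b[:, 0], b[:, 1], b[:, 2]
    A, B, C = t[:, 0], t[:, 1], t[:, 2]
    case = b1 < c
    tets = np.empty((len(bottom), 3, 4), dtype=np.int64)
    tets[case, 0] = np.stack([a[case], b1[case], c[case], C[case]], axis=1)
    tets[case, 1] = np.stack([a[case], b1[case], C[case], B[case]], axis=1)
    tets[case, 2] = np.stack([a[case], B[case], C[case], A[case]], axis=1)
    nc = ~case
    tets[nc, 0] = np.stack([a[nc], b1[nc], c[nc], B[nc]], axis=1)
    tets[nc, 1] = np.stack([a[nc], c[nc], C[nc], B[nc]], axis=1)
    tets[nc, 2] = np.stack([a[nc], C[nc], A[nc], B[nc]], axis=1)
    return tets.reshape(-1, 4)


def tube_volume_mesh(
    length: float,
    diameter: float,
    target_cell_size: float,
    n_layers: int = 0,
    axial_cell_size: float | None = None,
) -> VolumeMesh:
    """Structured swept tet mesh of a straight tube along +x from the origin.

    ``axial_cell_size`` decouples the axial spacing from the cross-section
    spacing; developed duct flow is axially smooth, so a radially fine,
    axially coarse mesh resolves the profile at a fraction of the cells.
    """
    if target_cell_size <= 0:
        raise ValueError("target_cell_size must be positive")
    R = diameter / 2.0
    disk = _disk_points(R, target_cell_size, n_layers)
    tri = Delaunay(disk).simplices
    n2 = len(disk)
    nz = max(2, int(round(length / (axial_cell_size or target_cell_size))))
    xs = np.linspace(0.0, length, nz + 1)
    points = np.concatenate(
        [np.column_stack([np.full(n2, x), disk[:, 0], disk[:, 1]]) for x in xs]
    )
    cells = []
    for k in range(nz):
        cells.append(_split_prisms(tri + k * n2, tri + (k + 1) * n2))
    cells = _orient_positive(points, np.vstack(cells))
    ifn, ifo, ifnb, bfn, bfo = _extract_faces(cells)
    centroids = points[bfn].mean(axis=1)
    tol = 1e-9 * max(length, R) + 1e-12
    patch = np.full(len(bfn), 2, dtype=int)
    patch[np.abs(centroids[:, 0]) < tol] = 0
    patch[np.abs(centroids[:, 0] - length) < tol] = 1
    return VolumeMesh(
        points=points,
        cells=cells,
        iface_nodes=ifn,
        iface_owner=ifo,
        iface_neigh=ifnb,
        bface_nodes=bfn,
        bface_owner=bfo,
        bface_patch=patch,
        patch_names=["inlet", "outlet_1", "wall"],
        metadata={
            "construction": "swept_tube",
            "target_cell_size": target_cell_size,
            "n_layers": n_layers,
            "length": length,
            "diameter": diameter,
        },
    )


# --------------------------------------------------------------------------
# Lattice tree mesh
# --------------------------------------------------------------------------


def _dedup(points: np.ndarray, spacing: float) -> np.ndarray:
    """Keep one point per hash cell of size ``spacing`` (deterministic)."""
    if len(points) == 0:
        return points
    key = np.floor(points / spacing).astype(np.int64)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    ks = key[order]
    new = np.ones(len(ks), dtype=bool)
    new[1:] = np.any(ks[1:] != ks[:-1], axis=1)
    return points[order[new]]


def tree_volume_mesh(
    tree: CenterlineTree,
    target_cell_size: float,
    n_layers: int = 1,
    seed: int = 0,
) -> VolumeMesh:
    """Lattice/Delaunay tet mesh of a bifurcating tree's implicit solid."""
    h = target_cell_size
    if h <= 0:
        raise ValueError("target_cell_size must be positive")
    rng = np.random.default_rng(seed)
    caps = cap_specs(tree)

    layer_depths: list[float] = []
    if n_layers > 0:
        d = 0.35 * h
        for _ in range(n_layers):
            layer_depths.append(d)
            d *= 1.6
    depth_max = layer_depths[-1] if layer_depths else 0.0

    ends = np.array([s.start for s in tree.segments] + [s.end for s in tree.segments])
    lo = ends.min(axis=0) - (tree.max_radius + 2 * h)
    hi = ends.max(axis=0) + (tree.max_radius + 2 * h)
    # body-centred cubic lattice: its Delaunay tets are uniformly well
    # shaped, so the bulk mesh carries no slivers; constant chosen to give
    # about the same cell count as a cubic lattice of pitch h
    a = 1.26 * h
    shape = np.ceil((hi - lo) / a).astype(int) + 1
    axes = [lo[k] + a * np.arange(shape[k]) for k in range(3)]
    corners = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    lattice = np.vstack([corners, corners + 0.5 * a])
    lattice = lattice + rng.uniform(-0.08, 0.08, size=lattice.shape) * a
    sdf = tree_signed_distance(tree, lattice)

    interior = lattice[sdf < -(depth_max + 0.5 * h)]

    near = lattice[(sdf > -(depth_max + 0.6 * h)) & (sdf < 0.9 * h)]
    surf_pts = project_to_surface(tree, near) if len(near) else np.zeros((0, 3))
    surf_pts = _dedup(surf_pts, 0.8 * h)
    # tangential relaxation: projection bunches points on high-curvature
    # carina ridges, which breeds tiny flat wall cells there
    from scipy.spatial import cKDTree

    for _ in range(2):
        if len(surf_pts) < 8:
            break
        kdt = cKDTree(surf_pts)
        pairs = kdt.query_pairs(1.4 * h, output_type="ndarray")
        if len(pairs) == 0:
            break
        acc = np.zeros_like(surf_pts)
        cnt = np.zeros(len(surf_pts))
        for c in range(3):
            acc[:, c] += np.bincount(pairs[:, 0], surf_pts[pairs[:, 1], c], minlength=len(surf_pts))
            acc[:, c] += np.bincount(pairs[:, 1], surf_pts[pairs[:, 0], c], minlength=len(surf_pts))
        cnt += np.bincount(pairs[:, 0], minlength=len(surf_pts))
        cnt += np.bincount(pairs[:, 1], minlength=len(surf_pts))
        has = cnt > 0
        target = surf_pts.copy()
        target[has] = acc[has] / cnt[has, None]
        surf_pts = project_to_surface(tree, surf_pts + 0.5 * (target - surf_pts))

    shells = []
    if layer_depths and len(surf_pts):
        normals = signed_distance_gradient(tree, surf_pts)
        normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
        for d in layer_depths:
            cand = surf_pts - d * normals
            inside = tree_signed_distance(tree, cand) < -0.2 * d
            shells.append(cand[inside])

    # every cap gets a short structured sleeve (stacked disks swept inward
    # along the branch axis): boundary cells at inlets/outlets then have the
    # same quality as a swept tube mesh, which keeps the pressure-velocity
    # coupling well behaved right at the caps
    sleeve_depths = np.array([0.0, 0.7, 1.4]) * h
    clear_depth = 1.85 * h
    cap_pts_all = []

    def _outside_sleeves(pts: np.ndarray) -> np.ndarray:
        keep = np.ones(len(pts), dtype=bool)
        for cap in caps:
            s = (pts - cap.point) @ cap.outward_normal
            radial = np.linalg.norm(
                pts - cap.point - s[:, None] * cap.outward_normal, axis=1
            )
            keep &= ~((s > -clear_depth) & (radial < cap.radius + 0.8 * h))
        return keep

    interior = interior[_outside_sleeves(interior)]
    surf_pts = surf_pts[_outside_sleeves(surf_pts)]
    shells = [sh[_outside_sleeves(sh)] for sh in shells]
    for cap in caps:
        disk = _disk_points(cap.radius, 0.8 * h)
        e1, e2 = _frame(cap.outward_normal)
        ring = cap.point + disk[:, :1] * e1 + disk[:, 1:] * e2
        for depth in sleeve_depths:
            layer = ring - depth * cap.outward_normal
            if depth > 0:
                # break the exact coplanarity that degenerates the Delaunay;
                # the cap plane itself stays exact
                layer = layer + rng.uniform(-0.08, 0.08, size=layer.shape) * h
            cap_pts_all.append(layer)

    points = np.vstack([interior, surf_pts, *cap_pts_all, *shells])
    movable = np.zeros(len(points), dtype=bool)
    movable[: len(interior)] = True

    # Lloyd-style smoothing of the interior lattice points: pulls the flat
    # sliver tets out of the transition band between near-wall shells and
    # the bulk lattice, which the pressure-velocity coupling cannot tolerate
    for _ in range(2):
        tets = Delaunay(points).simplices
        e = np.vstack([tets[:, [a, b]] for a in range(4) for b in range(a + 1, 4)])
        e = np.unique(np.sort(e, axis=1), axis=0)
        acc = np.zeros_like(points)
        cnt = np.zeros(len(points))
        for c in range(3):
            acc[:, c] += np.bincount(e[:, 0], points[e[:, 1], c], minlength=len(points))
            acc[:, c] += np.bincount(e[:, 1], points[e[:, 0], c], minlength=len(points))
        cnt += np.bincount(e[:, 0], minlength=len(points))
        cnt += np.bincount(e[:, 1], minlength=len(points))
        target = acc / np.maximum(cnt, 1)[:, None]
        proposed = points.copy()
        proposed[movable] += 0.6 * (target[movable] - points[movable])
        ok = tree_signed_distance(tree, proposed[movable]) < -0.4 * h
        idx = np.flatnonzero(movable)
        points[idx[ok]] = proposed[idx[ok]]

    cells = Delaunay(points).simplices.astype(np.int64)
    cells = _orient_positive(points, cells)

    centroids = points[cells].mean(axis=1)
    cd = tree_signed_distance(tree, centroids)
    p = points[cells]
    edges = np.stack(
        [
            p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0],
            p[:, 2] - p[:, 1], p[:, 3] - p[:, 1], p[:, 3] - p[:, 2],
        ],
        axis=1,
    )
    lmax = np.linalg.norm(edges, axis=2).max(axis=1)
    vols = _tet_volumes(points, cells)
    areas = np.zeros(len(cells))
    for a, b, c in _TET_FACES:
        areas += 0.5 * np.linalg.norm(
            np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]), axis=1
        )
    inradius = 3.0 * np.abs(vols) / np.maximum(areas, 1e-300)
    # only essentially degenerate near-boundary cells are dropped (keeping
    # the wall smooth); moderately flat cells are handled downstream by
    # control-volume agglomeration in the flow solver
    # only exterior bridge tets are excluded; flat or tiny interior cells
    # stay in the mesh (dropping them would slit the wall into crevices)
    # and are agglomerated into healthy neighbours by the flow solver
    keep = (lmax < 2.6 * h) & (cd < -0.01 * h)
    cells = cells[keep]
    cells = cells[_connected_filter(cells)]

    used = np.unique(cells)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    points = points[used]
    cells = remap[cells]

    ifn, ifo, ifnb, bfn, bfo = _extract_faces(cells)
    bc = points[bfn].mean(axis=1)
    av = 0.5 * np.cross(
        points[bfn[:, 1]] - points[bfn[:, 0]], points[bfn[:, 2]] - points[bfn[:, 0]]
    )
    bnormals = av / np.maximum(np.linalg.norm(av, axis=1, keepdims=True), 1e-300)
    patch = np.full(len(bfn), len(caps), dtype=int)
    for ci, cap in enumerate(caps):
        s = (bc - cap.point) @ cap.outward_normal
        radial = np.linalg.norm(bc - cap.point - s[:, None] * cap.outward_normal, axis=1)
        on_cap = (
            (np.abs(s) < 0.3 * h)
            & (radial < cap.radius + 0.5 * h)
            & (bnormals @ cap.outward_normal > 0.5)
        )
        patch[on_cap] = ci

    patch_names = [c.name for c in caps] + ["wall"]
    mesh = VolumeMesh(
        points=points,
        cells=cells,
        iface_nodes=ifn,
        iface_owner=ifo,
        iface_neigh=ifnb,
        bface_nodes=bfn,
        bface_owner=bfo,
        bface_patch=patch,
        patch_names=patch_names,
        metadata={
            "construction": "lattice_delaunay",
            "target_cell_size": h,
            "n_layers": n_layers,
            "seed": seed,
        },
    )
    for name in patch_names[:-1]:
        if len(mesh.patch_faces(name)) == 0:
            raise MeshingError(f"cap patch {name!r} received no boundary faces")
    if np.any(mesh.cell_volumes <= 0):
        raise MeshingError("non-positive cell volume after filtering")
    return mesh


def generate_volume_mesh(
    surface: AirwaySurface,
    target_cell_size: float,
    n_layers: int = 1,
    seed: int = 0,
) -> VolumeMesh:
    """Volume-mesh the solid bounded by a watertight airway surface.

    Single straight tubes are swept; bifurcating trees use the lattice
    construction fitted to the tree's signed-distance field.
    """
    tm = surface.as_trimesh()
    if not tm.is_watertight:
        raise MeshingError("input surface is not watertight")
    tree = surface.tree
    if len(tree.segments) == 1:
        seg = tree.root
        mesh = tube_volume_mesh(seg.length, 2 * seg.radius, target_cell_size, n_layers)
        if np.linalg.norm(seg.start) > 0 or abs(seg.direction[0] - 1.0) > 1e-12:
            e1, e2 = _frame(seg.direction)
            basis = np.stack([seg.direction, e1, e2], axis=1)
            mesh.points = (mesh.points @ basis.T) + seg.start
            mesh.metadata.pop("_volumes", None)
            mesh.metadata.pop("_centroids", None)
    else:
        mesh = tree_volume_mesh(tree, target_cell_size, n_layers, seed)
    mesh.metadata["tree_ref"] = tree
    return mesh


# --------------------------------------------------------------------------
# Mesh-independence machinery
# --------------------------------------------------------------------------


def probe_average_velocity(solution, probe_set: ProbeSet) -> float:
    """Mean velocity magnitude over the probe path points (flow-path metric)."""
    u = solution.sample_velocity(probe_set.path_points)
    return float(np.mean(np.linalg.norm(u, axis=1)))


def grid_convergence_index(
    f_coarse: float,
    f_fine: float,
    refinement_ratio: float,
    order: float,
    safety_factor: float = 1.25,
) -> float:
    """GCI = F_s |(f_coarse - f_fine)/f_fine| / (r^p - 1)."""
    if refinement_ratio <= 1:
        raise ValueError("refinement ratio must exceed 1")
    if order <= 0:
        raise ValueError("order must be positive")
    if f_fine == 0:
        raise ZeroDivisionError("fine-grid value is zero; GCI undefined")
    return safety_factor * abs((f_coarse - f_fine) / f_fine) / (
        refinement_ratio**order - 1.0
    )


@dataclass
class MeshStudyResult:
    levels: list[tuple[int, float]]  # (cell count, probe metric m/s)
    relative_changes: list[float]
    gci_values: list[float]
    selected_level: int
    tolerance_met: bool
    observed_order: float | None = None

    @property
    def selected_metric(self) -> float:
        return self.levels[self.selected_level][1]


def mesh_independence_study(
    surface: AirwaySurface,
    size_ladder: Sequence[float],
    solve_fn: Callable,
    probe_set: ProbeSet,
    tolerance: float = 0.003,
    n_layers: int = 1,
    seed: int = 0,
) -> MeshStudyResult:
    """Solve on a ladder of meshes and pick the coarsest converged level.

    ``solve_fn(mesh)`` may return a flow solution (probed for the mean
    velocity along the flow path line) or a bare scalar metric.  If no
    level meets the tolerance the finest is selected and flagged.
    """
    sizes = list(size_ladder)
    if len(sizes) < 2:
        raise ValueError("need at least two ladder levels")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("size ladder must be strictly decreasing")
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")

    levels: list[tuple[int, float]] = []
    for size in sizes:
        mesh = generate_volume_mesh(surface, size, n_layers=n_layers, seed=seed)
        result = solve_fn(mesh)
        metric = (
            float(result)
            if isinstance(result, (int, float, np.floating))
            else probe_average_velocity(result, probe_set)
        )
        levels.append((mesh.n_cells, metric))

    changes = [
        abs(m1 - m0) / abs(m1) if m1 != 0 else abs(m1 - m0)
        for (_, m0), (_, m1) in zip(levels, levels[1:])
    ]
    order: float | None = None
    if len(levels) >= 3:
        (n0, f0), (n1, f1), (n2, f2) = levels[-3:]
        r = ((n2 / n1) ** (1 / 3) + (n1 / n0) ** (1 / 3)) / 2
        num, den = f0 - f1, f1 - f2
        if r > 1 and den != 0 and num / den > 0:
            order = math.log(num / den) / math.log(r)
    gci = []
    for (n0, f0), (n1, f1) in zip(levels, levels[1:]):
        r = max((n1 / n0) ** (1 / 3), 1.0 + 1e-9)
        p = order if (order is not None and order > 0.5) else 2.0
        gci.append(grid_convergence_index(f0, f1, r, p) if f1 != 0 else 0.0)

    selected = None
    for i, ch in enumerate(changes):
        if ch <= tolerance:
            selected = i
            break
    tolerance_met = selected is not None
    if selected is None:
        selected = len(levels) - 1
    return MeshStudyResult(levels, changes, gci, selected, tolerance_met, order)


def export_mesh(mesh: VolumeMesh, path, fmt: str = "vtu"):
    """Write the mesh as VTU or Gmsh MSH (patch labels preserved in MSH)."""
    from . import io_vtk

    fmt = fmt.lower()
    if fmt == "vtu":
        return io_vtk.write_vtu(path, mesh.points, mesh.cells)
    if fmt == "msh":
        return io_vtk.write_msh(
            path,
            mesh.points,
            mesh.cells,
            mesh.bface_nodes,
            mesh.bface_patch,
            mesh.patch_names,
        )
    raise ValueError(f"unsupported mesh format {fmt!r}; use 'vtu' or 'msh'")
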