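"""Parametric bifurcating airway geometry (generations G6-G9).

Builds symmetric, in-plane, four-generation tracheobronchial trees for an
infant (6 months), child (5 years) and adult (25 years) from tabulated
per-generation dimensions (length L, diameter D, outer curvature radius R,
carinal curvature radius r; bifurcation angle 70 deg), and turns them into
watertight labelled triangulated surfaces.

The solid is modelled implicitly: each branch is a cylinder (flat-capped at
the tree inlet/outlets, ball-ended at junctions) and branches are joined by
smoothed boolean unions.  The smoothing radius at the ridge between the two
daughters approximates the carinal rounding r, and the parent-daughter
blend approximates the outer-wall transition; the exact CAD construction
behind published models of this family is not standardised, so this is a
reproducible stand-in parameterised by the same r and R.

Layout convention: the G6 root runs along +x from the origin, the
bifurcation plane is z = 0, and the "right" daughter of every bifurcation
is the one deviating toward negative y.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GenerationDims",
    "AgeProfile",
    "Segment",
    "CenterlineTree",
    "AirwaySurface",
    "SectionProbe",
    "ProbeSet",
    "SurfaceConstructionError",
    "build_profile",
    "interpolate_profile",
    "build_centerline_tree",
    "build_tree_from_levels",
    "tree_signed_distance",
    "signed_distance_gradient",
    "project_to_surface",
    "build_surface",
    "make_probe_set",
    "export_surface",
    "cap_specs",
    "classify_cap",
]


class SurfaceConstructionError(RuntimeError):
    """Raised when a generated surface fails watertightness/manifold checks."""


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GenerationDims:
    """Dimensions of one airway generation (all in mm).

    ``outer_curvature_mm`` (R) and ``carinal_radius_mm`` (r) describe the
    bifurcation at the *distal* end of this generation and are absent for
    the last generation, which does not bifurcate within the model.
    """

    generation_index: int
    length_mm: float
    diameter_mm: float
    outer_curvature_mm: float | None = None
    carinal_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("length and diameter must be strictly positive")
        for v in (self.outer_curvature_mm, self.carinal_radius_mm):
            if v is not None and v <= 0:
                raise ValueError("curvature radii must be strictly positive when present")
        r = self.carinal_radius_mm
        if r is not None and r >= self.diameter_mm / 2.0:
            raise ValueError("carinal radius must be smaller than the branch radius")


@dataclass(frozen=True)
class AgeProfile:
    """Geometric genome of one age group: four generations plus the angle."""

    name: str
    dims: tuple[GenerationDims, GenerationDims, GenerationDims, GenerationDims]
    bifurcation_angle_deg: float = 70.0

    def __post_init__(self) -> None:
        gens = [d.generation_index for d in self.dims]
        if gens != sorted(gens) or len(set(gens)) != len(gens):
            raise ValueError("generations must be distinct and increasing")
        if gens != [6, 7, 8, 9] and len(gens) != 4:
            raise ValueError("profile must cover four consecutive generations")
        if gens != list(range(gens[0], gens[0] + 4)):
            raise ValueError("generations must be consecutive")
        diam = [d.diameter_mm for d in self.dims]
        if any(b >= a for a, b in zip(diam, diam[1:])):
            raise ValueError("diameter must decrease strictly with generation")
        if not 0 < self.bifurcation_angle_deg < 180:
            raise ValueError("bifurcation angle must be in (0, 180) degrees")

    def generation(self, g: int) -> GenerationDims:
        for d in self.dims:
            if d.generation_index == g:
                return d
        raise KeyError(f"generation {g} not in profile {self.name!r}")


# Per-generation (L, D, R, r) in mm for the three age groups; the last
# generation of the model window does not bifurcate, hence no R/r.
_TABLE: dict[str, list[tuple[int, float, float, float | None, float | None]]] = {
    "infant": [
        (6, 3.5, 1.0, 1.8, 0.09),
        (7, 2.9, 0.9, 1.4, 0.07),
        (8, 2.5, 0.7, 1.2, 0.06),
        (9, 2.1, 0.6, None, None),
    ],
    "child": [
        (6, 5.6, 1.8, 3.0, 0.15),
        (7, 4.7, 1.5, 2.4, 0.12),
        (8, 4.0, 1.2, 2.0, 0.10),
        (9, 3.3, 1.0, None, None),
    ],
    "adult": [
        (6, 8.8, 2.8, 4.6, 0.23),
        (7, 7.4, 2.3, 3.6, 0.18),
        (8, 6.3, 1.8, 3.0, 0.15),
        (9, 5.3, 1.5, None, None),
    ],
}

_ANCHOR_AGES: list[tuple[float, str]] = [(0.5, "infant"), (5.0, "child"), (25.0, "adult")]


def build_profile(name: str) -> AgeProfile:
    """Embedded G6-G9 dimensions for ``infant``, ``child`` or ``adult``."""
    try:
        rows = _TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown age group {name!r}; expected one of {sorted(_TABLE)}"
        ) from None
    return AgeProfile(name, tuple(GenerationDims(*row) for row in rows))


def interpolate_profile(age_years: float) -> AgeProfile:
    """Per-field linear interpolation between the anchor ages 0.5, 5 and 25."""
    lo, hi = _ANCHOR_AGES[0][0], _ANCHOR_AGES[-1][0]
    if not lo <= age_years <= hi:
        raise ValueError(f"age {age_years} outside supported range [{lo}, {hi}] years")
    for (a0, n0), (a1, n1) in zip(_ANCHOR_AGES, _ANCHOR_AGES[1:]):
        if age_years <= a1:
            w = (age_years - a0) / (a1 - a0)
            if w == 0.0:
                return build_profile(n0)
            if w == 1.0:
                return build_profile(n1)
            rows = []
            for r0, r1 in zip(_TABLE[n0], _TABLE[n1]):
                lerp = [r0[0]]
                for v0, v1 in zip(r0[1:], r1[1:]):
                    lerp.append(None if v0 is None else v0 + w * (v1 - v0))
                rows.append(GenerationDims(*lerp))
            return AgeProfile(f"age_{age_years:g}y", tuple(rows))
    raise AssertionError("unreachable")


# --------------------------------------------------------------------------
# Centerline tree
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One straight branch of the centerline tree (SI meters)."""

    index: int
    parent: int  # -1 for the root
    generation_index: int
    start: np.ndarray  # (3,)
    end: np.ndarray
    radius: float
    direction: np.ndarray  # unit
    children: tuple[int, ...]
    # Rounding radii of the bifurcation at this segment's distal end (m);
    # None at leaves.
    carinal_radius: float | None = None
    outer_curvature: float | None = None

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class CenterlineTree:
    """Planar symmetric binary tree of straight segments (z = 0 plane)."""

    segments: tuple[Segment, ...]
    bifurcation_angle_deg: float
    profile: AgeProfile | None = None

    @property
    def root(self) -> Segment:
        return self.segments[0]

    @property
    def leaves(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if not s.children)

    @property
    def max_radius(self) -> float:
        return max(s.radius for s in self.segments)

    @property
    def min_diameter(self) -> float:
        return 2.0 * min(s.radius for s in self.segments)

    def of_generation(self, g: int) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.generation_index == g)

    def right_segment(self, g: int) -> Segment:
        """Right-most segment of generation g: right daughter at every split."""
        seg = self.root
        while seg.generation_index < g:
            kids = [self.segments[i] for i in seg.children]
            # right = more negative y deviation
            seg = min(kids, key=lambda s: float(s.direction[1]))
        if seg.generation_index != g:
            raise ValueError(f"generation {g} not reachable in tree")
        return seg

    def leaf_ancestors(self, leaf_index: int) -> list[int]:
        chain = []
        i = leaf_index
        while i != -1:
            chain.append(i)
            i = self.segments[i].parent
        return chain[::-1]


def _rot_z(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def build_tree_from_levels(
    levels: list[tuple[float, float, float | None, float | None]],
    bifurcation_angle_deg: float = 70.0,
    first_generation_index: int = 0,
    profile: AgeProfile | None = None,
) -> CenterlineTree:
    """Binary tree from per-level (L, D, R, r) in meters, root along +x.

    Level k holds 2**k identical segments; daughters deviate by half the
    bifurcation angle to either side of the parent direction, in z = 0.
    """
    half = math.radians(bifurcation_angle_deg / 2.0)
    segments: list[dict] = []

    def add(level: int, parent: int, start: np.ndarray, direction: np.ndarray) -> int:
        length, diameter, r_outer, r_car = levels[level]
        idx = len(segments)
        segments.append(
            dict(
                index=idx,
                parent=parent,
                generation_index=first_generation_index + level,
                start=start,
                end=start + direction * length,
                radius=diameter / 2.0,
                direction=direction,
                children=[],
                carinal_radius=r_car,
                outer_curvature=r_outer,
            )
        )
        if level + 1 < len(levels):
            end = segments[idx]["end"]
            for sign in (+1.0, -1.0):
                child = add(level + 1, idx, end, _rot_z(direction, sign * half))
                segments[idx]["children"].append(child)
        return idx

    add(0, -1, np.zeros(3), np.array([1.0, 0.0, 0.0]))
    frozen = tuple(
        Segment(
            index=s["index"],
            parent=s["parent"],
            generation_index=s["generation_index"],
            start=s["start"],
            end=s["end"],
            radius=s["radius"],
            direction=s["direction"],
            children=tuple(s["children"]),
            carinal_radius=s["carinal_radius"],
            outer_curvature=s["outer_curvature"],
        )
        for s in segments
    )
    return CenterlineTree(frozen, bifurcation_angle_deg, profile)


def build_centerline_tree(profile: AgeProfile) -> CenterlineTree:
    """Centerline tree of a four-generation age profile (mm converted to m)."""
    levels = []
    for d in profile.dims:
        levels.append(
            (
                d.length_mm * 1e-3,
                d.diameter_mm * 1e-3,
                None if d.outer_curvature_mm is None else d.outer_curvature_mm * 1e-3,
                None if d.carinal_radius_mm is None else d.carinal_radius_mm * 1e-3,
            )
        )
    return build_tree_from_levels(
        levels,
        profile.bifurcation_angle_deg,
        first_generation_index=profile.dims[0].generation_index,
        profile=profile,
    )


# --------------------------------------------------------------------------
# Implicit solid
# --------------------------------------------------------------------------


def _smin(a: np.ndarray, b: np.ndarray, k: float | np.ndarray) -> np.ndarray:
    """Polynomial smooth minimum; rounds the crease where the surfaces meet.

    ``k`` may vary per point (used to localise blending to a junction).
    """
    k = np.asarray(k, dtype=float)
    safe = np.maximum(k, 1e-300)
    h = np.clip(k - np.abs(a - b), 0.0, None) / safe
    return np.minimum(a, b) - h * h * k * 0.25


def _segment_sdf(
    pts: np.ndarray, seg: Segment, round_start: bool, round_end: bool
) -> np.ndarray:
    rel = pts - seg.start
    t = rel @ seg.direction
    radial = np.linalg.norm(rel - t[:, None] * seg.direction, axis=1)
    dx = radial - seg.radius
    dz = np.maximum(-t, t - seg.length)
    d = np.minimum(np.maximum(dx, dz), 0.0) + np.hypot(
        np.maximum(dx, 0.0), np.maximum(dz, 0.0)
    )
    if round_end:
        d = np.minimum(d, np.linalg.norm(pts - seg.end, axis=1) - seg.radius)
    if round_start:
        d = np.minimum(d, np.linalg.norm(pts - seg.start, axis=1) - seg.radius)
    return d


def _junction_blends(seg: Segment) -> tuple[float, float]:
    """(carina blend, outer blend) smoothing lengths for the distal junction.

    The carinal ridge is rounded on the scale of the tabulated carinal
    radius r; the parent-daughter outer corner on a scale tied to the outer
    curvature radius R but capped by the tube radius, so that mid-segment
    cross sections keep their tabulated diameter.
    """
    r_car = seg.carinal_radius if seg.carinal_radius is not None else 0.15 * seg.radius
    r_out = seg.outer_curvature if seg.outer_curvature is not None else seg.radius
    k_car = 2.0 * r_car
    k_out = min(0.6 * r_out, 0.8 * seg.radius)
    return k_car, k_out


def tree_signed_distance(
    tree: CenterlineTree, pts: np.ndarray, end_extension: float = 0.0
) -> np.ndarray:
    """Signed distance (negative inside) of the blended-union airway solid.

    ``end_extension`` lengthens the solid axially beyond the inlet/outlet
    cap planes; used internally so cap planes can be cut exactly.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))

    def eval_seg(i: int) -> np.ndarray:
        seg = tree.segments[i]
        if end_extension > 0.0 and (seg.parent < 0 or not seg.children):
            ext_start = end_extension if seg.parent < 0 else 0.0
            ext_end = end_extension if not seg.children else 0.0
            seg = Segment(
                index=seg.index,
                parent=seg.parent,
                generation_index=seg.generation_index,
                start=seg.start - ext_start * seg.direction,
                end=seg.end + ext_end * seg.direction,
                radius=seg.radius,
                direction=seg.direction,
                children=seg.children,
                carinal_radius=seg.carinal_radius,
                outer_curvature=seg.outer_curvature,
            )
        d = _segment_sdf(pts, seg, round_start=seg.parent >= 0, round_end=bool(seg.children))
        if seg.children:
            k_car, k_out = _junction_blends(seg)
            # blend only near this junction so far-apart branches of
            # different subtrees never interact
            reach = 4.0 * seg.radius
            fade = np.clip(1.0 - np.linalg.norm(pts - seg.end, axis=1) / reach, 0.0, 1.0)
            c1, c2 = seg.children
            d_children = _smin(eval_seg(c1), eval_seg(c2), k_car * fade)
            d = _smin(d, d_children, k_out * fade)
        return d

    return eval_seg(tree.root.index)


def signed_distance_gradient(
    tree: CenterlineTree, pts: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    grad = np.empty_like(pts)
    for ax in range(3):
        dp = np.zeros(3)
        dp[ax] = eps
        grad[:, ax] = (
            tree_signed_distance(tree, pts + dp) - tree_signed_distance(tree, pts - dp)
        ) / (2 * eps)
    return grad


def project_to_surface(
    tree: CenterlineTree, pts: np.ndarray, iterations: int = 3
) -> np.ndarray:
    """Newton projection of points onto the zero level set."""
    p = np.array(np.atleast_2d(pts), dtype=float)
    for _ in range(iterations):
        d = tree_signed_distance(tree, p)
        g = signed_distance_gradient(tree, p)
        norm2 = np.maximum(np.einsum("ij,ij->i", g, g), 1e-12)
        p -= (d / norm2)[:, None] * g
    return p


# --------------------------------------------------------------------------
# Caps
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CapSpec:
    name: str
    point: np.ndarray
    outward_normal: np.ndarray
    radius: float
    segment_index: int


def cap_specs(tree: CenterlineTree) -> list[CapSpec]:
    """Inlet (root start) and outlet_1..N (leaf tips) cap planes.

    Outlets are numbered deterministically by descending tip-y then tip-x.
    """
    caps = [
        CapSpec("inlet", tree.root.start.copy(), -tree.root.direction, tree.root.radius, tree.root.index)
    ]
    leaves = sorted(
        tree.leaves, key=lambda s: (-round(float(s.end[1]), 9), round(float(s.end[0]), 9))
    )
    for k, leaf in enumerate(leaves, start=1):
        caps.append(CapSpec(f"outlet_{k}", leaf.end.copy(), leaf.direction, leaf.radius, leaf.index))
    return caps


def classify_cap(
    caps: list[CapSpec],
    centroids: np.ndarray,
    normals: np.ndarray | None,
    plane_tol: float,
    normal_tol: float = 0.7,
) -> np.ndarray:
    """Cap index per facet (-1 = wall) from centroid/normal proximity tests."""
    n = len(centroids)
    out = np.full(n, -1, dtype=int)
    for ci, cap in enumerate(caps):
        s = (centroids - cap.point) @ cap.outward_normal
        radial = np.linalg.norm(
            centroids - cap.point - s[:, None] * cap.outward_normal, axis=1
        )
        hit = (np.abs(s) <= plane_tol) & (radial <= cap.radius + plane_tol)
        if normals is not None:
            hit &= normals @ cap.outward_normal > normal_tol
        out[hit & (out == -1)] = ci
    return out


# --------------------------------------------------------------------------
# Surface
# --------------------------------------------------------------------------


@dataclass
class AirwaySurface:
    """Watertight labelled triangulated boundary of the airway solid.

    ``patch`` holds, per triangle, an index into ``patch_names``; the last
    entry of ``patch_names`` is always ``wall``.
    """

    vertices: np.ndarray  # (nv, 3) m
    triangles: np.ndarray  # (nt, 3) int
    patch: np.ndarray  # (nt,) int
    patch_names: list[str]
    tree: CenterlineTree
    metadata: dict = field(default_factory=dict)

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def patch_triangles(self, name: str) -> np.ndarray:
        idx = self.patch_names.index(name)
        return self.triangles[self.patch == idx]

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
        )

    def patch_area(self, name: str) -> float:
        idx = self.patch_names.index(name)
        return float(self.triangle_areas()[self.patch == idx].sum())

    @property
    def enclosed_volume(self) -> float:
        return float(self.as_trimesh().volume)


def _tube_surface(tree: CenterlineTree, edge: float) -> AirwaySurface:
    """Analytic swept surface for a degenerate single-segment tree."""
    seg = tree.root
    R, L = seg.radius, seg.length
    n_theta = max(12, int(round(2 * math.pi * R / edge)))
    n_ax = max(2, int(round(L / edge)))
    # ring radius inflated so the polygon area matches the disk
    a = R * math.sqrt(2 * math.pi / (n_theta * math.sin(2 * math.pi / n_theta)))
    theta = np.arange(n_theta) * 2 * math.pi / n_theta
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1) * a
    # orthonormal frame
    d = seg.direction
    e1 = np.array([0.0, 1.0, 0.0]) if abs(d[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    verts = [seg.start, seg.end]
    for i in range(n_ax + 1):
        x = seg.start + d * (L * i / n_ax)
        for c1, c2 in ring:
            verts.append(x + c1 * e1 + c2 * e2)
    verts = np.array(verts)

    tris, patch = [], []
    base = 2

    def ring_idx(i, j):
        return base + i * n_theta + (j % n_theta)

    for j in range(n_theta):  # inlet fan (outward normal -d)
        tris.append([0, ring_idx(0, j + 1), ring_idx(0, j)])
        patch.append(0)
    for j in range(n_theta):  # outlet fan (+d)
        tris.append([1, ring_idx(n_ax, j), ring_idx(n_ax, j + 1)])
        patch.append(1)
    for i in range(n_ax):
        for j in range(n_theta):
            a0, a1 = ring_idx(i, j), ring_idx(i, j + 1)
            b0, b1 = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
            tris.append([a0, a1, b1])
            tris.append([a0, b1, b0])
            patch += [2, 2]
    return AirwaySurface(
        vertices=verts,
        triangles=np.array(tris, dtype=np.int64),
        patch=np.array(patch, dtype=int),
        patch_names=["inlet", "outlet_1", "wall"],
        tree=tree,
        metadata={"construction": "swept", "edge_length": edge},
    )


def build_surface(
    tree: CenterlineTree,
    profile: AgeProfile | None = None,
    resolution: float = 0.1,
) -> AirwaySurface:
    """Triangulate the airway solid boundary and label inlet/outlet/wall.

    ``resolution`` is the target surface edge length as a fraction of the
    smallest branch diameter.  Multi-branch trees are contoured from the
    signed distance field (marching cubes); single tubes use an exact swept
    triangulation.  Raises :class:`SurfaceConstructionError` if the result
    is not a closed manifold.
    """
    import trimesh
    from skimage.measure import marching_cubes

    if resolution <= 0 or resolution > 0.5:
        raise ValueError("resolution must be in (0, 0.5]")
    edge = resolution * tree.min_diameter
    if len(tree.segments) == 1:
        surface = _tube_surface(tree, edge)
    else:
        pitch = 0.9 * edge
        pts = np.array([s.start for s in tree.segments] + [s.end for s in tree.segments])
        lo = pts.min(axis=0) - (tree.max_radius + 3 * pitch)
        hi = pts.max(axis=0) + (tree.max_radius + 3 * pitch)
        ext = 3 * pitch
        lo -= ext
        hi += ext
        shape = np.ceil((hi - lo) / pitch).astype(int) + 1
        axes = [lo[k] + pitch * np.arange(shape[k]) for k in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vol = tree_signed_distance(tree, grid, end_extension=ext).reshape(shape)
        verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(pitch, pitch, pitch))
        verts = verts + lo
        tm = trimesh.Trimesh(verts, faces, process=True)
        f = np.asarray(tm.faces)
        nondegenerate = (
            (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
        )
        if not np.all(nondegenerate):
            tm = trimesh.Trimesh(tm.vertices, f[nondegenerate], process=False)
        if not tm.is_watertight:
            raise SurfaceConstructionError(
                "marching-cubes surface is not watertight; refine the resolution"
            )
        if tm.volume < 0:
            tm.invert()
        # Cut the over-long solid open at each cap plane, then close each
        # cut loop with a flat fan, so caps are exactly planar and normal
        # to the branch axis.
        caps = cap_specs(tree)
        vertices = np.asarray(tm.vertices, dtype=float)
        faces = np.asarray(tm.faces, dtype=np.int64)
        for cap in caps:
            vertices, faces = _clip_cap_sleeve(vertices, faces, cap, pitch)
        patch_names = [c.name for c in caps] + ["wall"]
        patch = [np.full(len(faces), len(patch_names) - 1, dtype=int)]
        all_faces = [faces]
        extra_vertices = []
        loops = _boundary_loops(faces)
        for loop in loops:
            pts = vertices[loop]
            center = pts.mean(axis=0)
            ci = int(np.argmin([np.linalg.norm(center - c.point) for c in caps]))
            cap = caps[ci]
            cidx = len(vertices) + len(extra_vertices)
            extra_vertices.append(center)
            fan = np.array(
                [[cidx, loop[j], loop[(j + 1) % len(loop)]] for j in range(len(loop))],
                dtype=np.int64,
            )
            n = np.cross(
                vertices[fan[0, 1]] - center, vertices[fan[0, 2]] - center
            )
            if n @ cap.outward_normal < 0:
                fan = fan[:, [0, 2, 1]]
            all_faces.append(fan)
            patch.append(np.full(len(fan), ci, dtype=int))
        if extra_vertices:
            vertices = np.vstack([vertices, np.array(extra_vertices)])
        faces = np.vstack(all_faces)
        patch = np.concatenate(patch)
        tm = trimesh.Trimesh(vertices, faces, process=False)
        if not tm.is_watertight:
            raise SurfaceConstructionError("capped surface is not watertight")
        if tm.volume < 0:
            tm.invert()
        surface = AirwaySurface(
            vertices=np.asarray(tm.vertices, dtype=float),
            triangles=np.asarray(tm.faces, dtype=np.int64),
            patch=patch[: len(tm.faces)],
            patch_names=patch_names,
            tree=tree,
            metadata={"construction": "marching_cubes", "pitch": pitch, "edge_length": edge},
        )
    _validate_surface(surface)
    prof = profile or tree.profile
    surface.metadata.update(
        {
            "profile": prof.name if prof is not None else None,
            "bifurcation_angle_deg": tree.bifurcation_angle_deg,
            "resolution": resolution,
        }
    )
    return surface


def _clip_cap_sleeve(
    vertices: np.ndarray, faces: np.ndarray, cap: CapSpec, pitch: float
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the contoured sleeve beyond one cap plane, cutting crossing
    triangles exactly at the plane.

    Only geometry inside the cap's own cylindrical sleeve is affected, so
    other branches that happen to lie beyond the (infinite) plane survive.
    """
    n = cap.outward_normal
    s = (vertices - cap.point) @ n
    radial = np.linalg.norm(vertices - cap.point - s[:, None] * n, axis=1)
    # margin wide enough for contouring error, narrow enough to keep out of
    # the closest sibling branch
    remove = (s > 0.0) & (radial <= cap.radius + 1.5 * pitch)

    frm = remove[faces]
    n_rm = frm.sum(axis=1)
    keep_faces = list(faces[n_rm == 0])
    cut_faces = faces[(n_rm == 1) | (n_rm == 2)]

    new_vertices = [vertices]
    cut_cache: dict[tuple[int, int], int] = {}
    n_old = len(vertices)

    def cut_point(u: int, v: int) -> int:
        key = (u, v) if u < v else (v, u)
        idx = cut_cache.get(key)
        if idx is None:
            t = s[u] / (s[u] - s[v])
            p = vertices[u] + t * (vertices[v] - vertices[u])
            idx = n_old + len(cut_cache)
            cut_cache[key] = idx
            new_vertices.append(p[None, :])
        return idx

    for face in cut_faces:
        rm = remove[face]
        # rotate so the odd-one-out vertex is first, preserving winding
        if rm.sum() == 1:
            k = int(np.argmax(rm))
        else:
            k = int(np.argmin(rm))
        a, b, c = np.roll(face, -k)
        if rm.sum() == 1:
            p1, p2 = cut_point(a, b), cut_point(a, c)
            keep_faces.append(np.array([p1, b, c]))
            keep_faces.append(np.array([p1, c, p2]))
        else:
            p1, p2 = cut_point(a, b), cut_point(a, c)
            keep_faces.append(np.array([a, p1, p2]))

    return np.vstack(new_vertices), np.array(keep_faces, dtype=np.int64)


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered vertex loops of the open boundary of an oriented triangle mesh."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    order = np.lexsort((und[:, 1], und[:, 0]))
    und_sorted = und[order]
    new = np.ones(len(und_sorted), dtype=bool)
    new[1:] = np.any(und_sorted[1:] != und_sorted[:-1], axis=1)
    group = np.cumsum(new) - 1
    counts = np.bincount(group)
    single = counts[group] == 1
    boundary = edges[order[single]]
    nxt = {int(u): int(v) for u, v in boundary}
    loops = []
    while nxt:
        start, v = next(iter(nxt.items()))
        loop = [start]
        del nxt[start]
        while v != start:
            loop.append(v)
            v_next = nxt.pop(v)
            v = v_next
        loops.append(loop)
    return loops


def _validate_surface(surface: AirwaySurface) -> None:
    tm = surface.as_trimesh()
    if not tm.is_watertight:
        raise SurfaceConstructionError("surface is not watertight")
    if not tm.is_winding_consistent:
        raise SurfaceConstructionError("surface winding is inconsistent")
    if tm.volume <= 0:
        raise SurfaceConstructionError("surface encloses non-positive volume")
    n_caps = len(surface.patch_names) - 1
    for name in surface.patch_names[:-1]:
        if not np.any(surface.patch == surface.patch_names.index(name)):
            raise SurfaceConstructionError(f"cap patch {name!r} is empty")
    expected = len(surface.tree.leaves) + 1
    if n_caps != expected:
        raise SurfaceConstructionError(f"expected {expected} cap patches, found {n_caps}")


# --------------------------------------------------------------------------
# Probes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionProbe:
    """Mid-segment cross-section plane (normal along the branch axis)."""

    segment_index: int
    generation_index: int
    center: np.ndarray
    normal: np.ndarray
    radius: float


@dataclass(frozen=True)
class ProbeSet:
    mid_sections: tuple[SectionProbe, ...]
    path_points: np.ndarray  # (5, 3) on the right generation-7 axis
    path_segment_index: int


def make_probe_set(tree: CenterlineTree, path_generation: int | None = None) -> ProbeSet:
    """Mid-section per segment plus 5 interior points on the right G7 axis."""
    sections = tuple(
        SectionProbe(s.index, s.generation_index, s.midpoint, s.direction.copy(), s.radius)
        for s in tree.segments
    )
    if path_generation is None:
        path_generation = min(tree.root.generation_index + 1, tree.segments[-1].generation_index)
    seg = tree.right_segment(path_generation)
    fractions = np.arange(1, 6) / 6.0
    pts = seg.start[None, :] + fractions[:, None] * (seg.end - seg.start)[None, :]
    return ProbeSet(sections, pts, seg.index)


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------


def export_surface(surface: AirwaySurface, path: str | Path, fmt: str = "stl") -> Path:
    """Write the surface (binary STL or legacy VTK polydata) plus JSON sidecar.

    STL stores geometry only; per-triangle patch labels go to the sidecar
    (and, for VTK, to a CELL_DATA array as well).
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "stl":
        _write_stl(surface, path)
    elif fmt in ("vtk", "vtp", "polydata"):
        _write_vtk_polydata(surface, path)
    else:
        raise ValueError(f"unsupported surface format {fmt!r}; use 'stl' or 'vtk'")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = dict(surface.metadata)
    meta["patch_names"] = surface.patch_names
    meta["patch"] = surface.patch.tolist()
    sidecar.write_text(json.dumps(meta))
    return path


def _write_stl(surface: AirwaySurface, path: Path) -> None:
    v, t = surface.vertices, surface.triangles
    n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", len(t)))
        tri = np.zeros((len(t), 12), dtype="<f4")
        tri[:, 0:3] = n
        tri[:, 3:6] = v[t[:, 0]]
        tri[:, 6:9] = v[t[:, 1]]
        tri[:, 9:12] = v[t[:, 2]]
        attr = np.zeros(len(t), dtype="<u2")
        rec = np.empty(len(t), dtype=[("tri", "<f4", 12), ("attr", "<u2")])
        rec["tri"] = tri
        rec["attr"] = attr
        fh.write(rec.tobytes())


def _write_vtk_polydata(surface: AirwaySurface, path: Path) -> None:
    v, t = surface.vertices, surface.triangles
    lines = [
        "# vtk DataFile Version 3.0",
        "airway surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines += [" ".join(f"{x:.9e}" for x in p) for p in v]
    lines.append(f"POLYGONS {len(t)} {4 * len(t)}")
    lines += ["3 " + " ".join(map(str, tri)) for tri in t]
    lines.append(f"CELL_DATA {len(t)}")
    lines.append("SCALARS patch int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(p)) for p in surface.patch]
    path.write_text("\n".join(lines) + "\n")
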