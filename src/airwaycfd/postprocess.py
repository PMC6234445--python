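"""Derived quantities of a flow solution: velocities, pressure drop, wall
shear stress, streamlines, and the cross-age study report.

The quantities mirror what is conventionally reported for bifurcating
airway flows: the peak velocity magnitude and the generation it occurs
in, the area-averaged inlet gauge pressure (the "pressure drop", since
outlets are pinned at zero gauge), the wall-shear-stress field and its
maximum, per-generation mid-cross-section statistics, and streamline
splitting at bifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ProbeSet, SectionProbe
from .respiration import AIR, FluidProperties
from .solver import FlowSolution

__all__ = [
    "WallField",
    "SectionStats",
    "StreamlineSet",
    "CaseResult",
    "StudyReport",
    "REPORTED_VALUES",
    "section_stats",
    "max_velocity",
    "pressure_drop",
    "max_wall_pressure",
    "wall_shear_stress",
    "trace_streamlines",
    "build_report",
]

# Published reference values (m/s, Pa) for the three age groups and two
# breathing phases, used for the comparison columns of the study report.
REPORTED_VALUES: dict[tuple[str, str], dict[str, float]] = {
    ("infant", "inspiration"): {"max_velocity": 2.22, "pressure_drop": 11.15, "max_wss": 1.74},
    ("child", "inspiration"): {"max_velocity": 1.82, "pressure_drop": 6.54, "max_wss": 1.23},
    ("adult", "inspiration"): {"max_velocity": 1.41, "pressure_drop": 3.71, "max_wss": 0.66},
    ("infant", "expiration"): {"max_velocity": 1.49, "pressure_drop": 7.11, "max_wss": 0.44},
    ("child", "expiration"): {"max_velocity": 1.12, "pressure_drop": 3.45, "max_wss": 0.28},
    ("adult", "expiration"): {"max_velocity": 0.89, "pressure_drop": 1.99, "max_wss": 0.16},
}


# --------------------------------------------------------------------------
# Cross sections
# --------------------------------------------------------------------------


@dataclass
class SectionStats:
    """Per-mid-section velocity statistics (one row per tree segment)."""

    segment_index: np.ndarray
    generation_index: np.ndarray
    area: np.ndarray  # m^2
    average_velocity: np.ndarray  # area-weighted |u|, m/s
    center_velocity: np.ndarray  # |u| at the section centre, m/s
    flux: np.ndarray  # volumetric flow through the section, m^3/s

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": self.segment_index,
                "generation": self.generation_index,
                "area_m2": self.area,
                "avg_velocity_ms": self.average_velocity,
                "center_velocity_ms": self.center_velocity,
                "flux_m3s": self.flux,
            }
        )


def _clip_cells_by_plane(
    solution: FlowSolution, probe: SectionProbe
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polygon areas/centroids where the section plane cuts nearby cells.

    Returns (cell indices, polygon areas, polygon centroids).
    """
    mesh = solution.mesh
    geom = solution.geometry
    h = np.cbrt(geom.V.mean())
    c = mesh.cell_centroids  # tet level: the plane is clipped tet by tet
    s_c = (c - probe.center) @ probe.normal
    radial = np.linalg.norm(
        c - probe.center - s_c[:, None] * probe.normal, axis=1
    )
    cand = np.flatnonzero((np.abs(s_c) < 2.5 * h) & (radial < probe.radius * 1.25))
    if len(cand) == 0:
        raise ValueError("section plane does not intersect the mesh")
    pts = mesh.points
    areas, centroids, cells_out = [], [], []
    for ci in cand:
        tet = mesh.cells[ci]
        sv = (pts[tet] - probe.center) @ probe.normal
        if np.all(sv > 0) or np.all(sv < 0):
            continue
        poly = []
        for a in range(4):
            for b in range(a + 1, 4):
                if (sv[a] > 0) != (sv[b] > 0):
                    t = sv[a] / (sv[a] - sv[b])
                    poly.append(pts[tet[a]] + t * (pts[tet[b]] - pts[tet[a]]))
        poly = np.array(poly)
        if len(poly) < 3:
            continue
        ctr = poly.mean(axis=0)
        # fan area about the centroid (polygon vertices ordered by angle)
        rel = poly - ctr
        e1 = rel[0] / max(np.linalg.norm(rel[0]), 1e-300)
        e2 = np.cross(probe.normal, e1)
        ang = np.arctan2(rel @ e2, rel @ e1)
        poly = poly[np.argsort(ang)]
        rel = poly - ctr
        area = 0.5 * np.abs(
            np.cross(rel, np.roll(rel, -1, axis=0)).sum(axis=0) @ probe.normal
        )
        if area <= 0:
            continue
        areas.append(area)
        centroids.append(ctr)
        cells_out.append(ci)
    if not cells_out:
        raise ValueError("degenerate section: no cells cut by the plane")
    return np.array(cells_out), np.array(areas), np.array(centroids)


def _section_discrete_flux(solution: FlowSolution, probe: SectionProbe) -> float:
    """Exact discrete mass-conserving volumetric flux through a mid-branch
    section: the sum of face fluxes over the cut set of faces straddling
    the plane inside the branch (closed laterally by the no-slip wall)."""
    geom = solution.geometry
    side = (geom.C - probe.center) @ probe.normal > 0
    straddle = side[geom.o] != side[geom.n]
    rel = geom.fc - probe.center
    axial = rel @ probe.normal
    radial = np.linalg.norm(rel - axial[:, None] * probe.normal, axis=1)
    in_branch = (np.abs(axial) < probe.radius) & (radial < probe.radius * 1.5)
    pick = straddle & in_branch
    sign = np.where(side[geom.n[pick]], 1.0, -1.0)  # positive along the axis
    return float((sign * solution.face_flux[pick]).sum() / solution.fluid.density)


def section_stats(solution: FlowSolution, probe_set: ProbeSet) -> SectionStats:
    """Area-weighted velocity statistics on every mid-segment cross section.

    Averages and centre values come from clipping each tetrahedron against
    the plane and integrating the reconstructed velocity; the flux column
    uses the exact discrete cut-set flux, which inherits the solver's mass
    conservation.
    """
    grads = solution.velocity_gradients()
    seg_idx, gen_idx, area_l, avg_l, ctr_l, flux_l = [], [], [], [], [], []
    for probe in probe_set.mid_sections:
        tets, areas, centroids = _clip_cells_by_plane(solution, probe)
        cells = solution.geometry.tet_to_cell[tets]
        dx = centroids - solution.geometry.C[cells]
        u = solution.velocity[cells] + np.einsum("nck,nc->nk", grads[cells], dx)
        umag = np.linalg.norm(u, axis=1)
        total = areas.sum()
        seg_idx.append(probe.segment_index)
        gen_idx.append(probe.generation_index)
        area_l.append(total)
        avg_l.append(float((areas * umag).sum() / total))
        ctr_l.append(
            float(np.linalg.norm(solution.sample_velocity(probe.center[None, :])[0]))
        )
        flux_l.append(_section_discrete_flux(solution, probe))
    return SectionStats(
        np.array(seg_idx),
        np.array(gen_idx),
        np.array(area_l),
        np.array(avg_l),
        np.array(ctr_l),
        np.array(flux_l),
    )


# --------------------------------------------------------------------------
# Scalars
# --------------------------------------------------------------------------


def max_velocity(solution: FlowSolution) -> tuple[float, int]:
    """Peak cell velocity magnitude and the generation index it occurs in.

    A resolved velocity peak occupies a finite region, so the reported
    maximum is the volume-supported one: the largest magnitude carried by
    at least 0.1% of the domain volume.  Isolated cells above 1.5x their
    neighbourhood maximum are additionally capped (a physical field cannot
    jump that much between adjacent cells), so single-cell discretisation
    artifacts on coarse meshes cannot masquerade as the peak.
    """
    umag = np.linalg.norm(solution.velocity, axis=1)
    geom = solution.geometry
    o, n = geom.o, geom.n
    neighmax = np.zeros(geom.nc)
    np.maximum.at(neighmax, o, umag[n])
    np.maximum.at(neighmax, n, umag[o])
    despiked = np.minimum(umag, 1.5 * neighmax)
    order = np.argsort(despiked)[::-1]
    cum = np.cumsum(geom.V[order])
    k = int(np.searchsorted(cum, 1e-3 * geom.V.sum()))
    k = min(k, len(order) - 1)
    i = int(order[k])
    gen = _generation_of_point(solution, solution.geometry.C[i])
    return float(despiked[i]), gen


def _generation_of_point(solution: FlowSolution, point: np.ndarray) -> int:
    tree = solution.mesh.metadata.get("tree_ref")
    if tree is None:
        return -1
    best, best_d = -1, np.inf
    for seg in tree.segments:
        rel = point - seg.start
        t = float(np.clip(rel @ seg.direction, 0.0, seg.length))
        d = np.linalg.norm(point - (seg.start + t * seg.direction))
        if d < best_d:
            best_d, best = d, seg.generation_index
    return best


def pressure_drop(solution: FlowSolution, inlet_patches: Sequence[str] | None = None) -> float:
    """Area-averaged gauge pressure over the velocity-inlet patch(es).

    With every outlet pinned at zero gauge pressure this is the driving
    inlet-to-outlet pressure drop.
    """
    if inlet_patches is None:
        inlet_patches = [name for name, _, _ in solution.bcs.velocity_inlets]
    geom = solution.geometry
    grads = solution.pressure_gradients()
    total_a, total_pa = 0.0, 0.0
    for name in inlet_patches:
        faces = solution.mesh.patch_faces(name)
        own = geom.bo[faces]
        dx = geom.bfc[faces] - geom.C[own]
        pb = solution.pressure[own] + np.einsum("nc,nc->n", grads[own], dx)
        a = geom.barea[faces]
        total_a += a.sum()
        total_pa += (pb * a).sum()
    return float(total_pa / total_a)


def max_wall_pressure(solution: FlowSolution) -> float:
    geom = solution.geometry
    faces = solution.mesh.patch_faces("wall")
    own = geom.bo[faces]
    grads = solution.pressure_gradients()
    dx = geom.bfc[faces] - geom.C[own]
    pb = solution.pressure[own] + np.einsum("nc,nc->n", grads[own], dx)
    return float(pb.max())


# --------------------------------------------------------------------------
# Wall shear stress
# --------------------------------------------------------------------------


@dataclass
class WallField:
    """Per-wall-facet pressure and wall-shear-stress magnitude."""

    face_indices: np.ndarray
    centroids: np.ndarray
    areas: np.ndarray
    pressure: np.ndarray  # Pa
    wss: np.ndarray  # Pa, >= 0

    @property
    def max_wss(self) -> float:
        """Area-supported maximum: the largest stress carried by at least
        0.1% of the wall area, with isolated facets above 1.5x their
        neighbourhood capped (a resolved stress peak spans several
        facets; single-facet extrema on coarse meshes are artifacts)."""
        if len(self.wss) < 12:
            return float(self.wss.max())
        from scipy.spatial import cKDTree

        _, idx = cKDTree(self.centroids).query(self.centroids, k=9)
        neighmax = self.wss[idx[:, 1:]].max(axis=1)
        despiked = np.minimum(self.wss, 1.5 * neighmax)
        order = np.argsort(despiked)[::-1]
        cum = np.cumsum(self.areas[order])
        k = min(int(np.searchsorted(cum, 1e-3 * self.areas.sum())), len(order) - 1)
        return float(despiked[order[k]])

    def wss_quantile(self, q: float) -> float:
        return float(np.quantile(self.wss, q))


def wall_shear_stress(
    solution: FlowSolution,
    wall_patch: str = "wall",
    fluid: FluidProperties | None = None,
) -> WallField:
    """mu times the wall-tangential velocity gradient, per wall facet.

    The gradient is formed from the reconstructed tangential velocity a
    short distance into the flow (three wall-cell heights along the
    inward normal) over that distance; the wall value is zero by
    no-slip.  Sampling past the first cell avoids the locally inflated
    velocities that strongly stretched wall cells carry.
    """
    fluid = fluid or solution.fluid
    mu = fluid.dynamic_viscosity
    mesh = solution.mesh
    if wall_patch not in mesh.patch_names:
        raise ValueError(f"no patch named {wall_patch!r}")
    geom = solution.geometry
    faces = mesh.patch_faces(wall_patch)
    own = geom.bo[faces]
    nrm = geom.bSf[faces] / geom.barea[faces][:, None]
    dn = np.einsum("nc,nc->n", geom.db[faces], nrm)
    dn = np.maximum(dn, 1e-12)
    g = solution.velocity_gradients()

    def tangential_speed(delta: np.ndarray) -> np.ndarray:
        at = geom.bfc[faces] - delta[:, None] * nrm
        idx = solution.locate_cells(at)
        dx = at - geom.C[idx]
        u = solution.velocity[idx] + np.einsum("nck,nc->nk", g[idx], dx)
        u_t = u - np.einsum("nc,nc->n", u, nrm)[:, None] * nrm
        return np.linalg.norm(u_t, axis=1)

    # quadratic two-point wall gradient (exact for a parabolic profile
    # through the no-slip wall), removing the finite-depth bias a single
    # sample carries.  The curvature correction is capped at 25% over the
    # single-point estimate: larger corrections exceed anything the local
    # wall-distance-to-radius ratios here can produce and indicate noise.
    d1, d2 = 2.0 * dn, 4.0 * dn
    u1, u2 = tangential_speed(d1), tangential_speed(d2)
    quadratic = mu * np.maximum((u1 / d1) * d2 - (u2 / d2) * d1, 0.0) / (d2 - d1)
    single = mu * u1 / d1
    wss = np.minimum(quadratic, 1.25 * single)
    grads = solution.pressure_gradients()
    dx = geom.bfc[faces] - geom.C[own]
    pb = solution.pressure[own] + np.einsum("nc,nc->n", grads[own], dx)
    return WallField(
        face_indices=faces,
        centroids=geom.bfc[faces],
        areas=geom.barea[faces],
        pressure=pb,
        wss=wss,
    )


# --------------------------------------------------------------------------
# Streamlines
# --------------------------------------------------------------------------


@dataclass
class StreamlineSet:
    paths: list[np.ndarray]
    exit_patch: list[str]  # name or "" if the trace stalled
    split_fractions: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def completed_fraction(self) -> float:
        done = sum(1 for e in self.exit_patch if e.startswith("outlet") or e == "inlet")
        return done / max(len(self.exit_patch), 1)


def trace_streamlines(
    solution: FlowSolution,
    n_seeds: int = 120,
    seed_patch: str | None = None,
    max_steps: int = 4000,
    rng_seed: int = 0,
) -> StreamlineSet:
    """Integrate velocity-field paths from the inlet until an outlet is hit.

    Fixed-step second-order (midpoint) integration on the reconstructed
    linear velocity field; each path is labelled with its exit patch, and
    seed counts per daughter subtree give bifurcation split fractions.
    """
    mesh = solution.mesh
    geom = solution.geometry
    if seed_patch is None:
        seed_patch = solution.bcs.velocity_inlets[0][0]
    faces = mesh.patch_faces(seed_patch)
    rng = np.random.default_rng(rng_seed)
    areas = geom.barea[faces]
    pick = rng.choice(len(faces), size=n_seeds, p=areas / areas.sum())
    # seeds slightly inside the domain
    nrm = geom.bSf[faces] / areas[:, None]
    h = np.cbrt(geom.V.mean())
    seeds = geom.bfc[faces[pick]] - 0.5 * h * nrm[pick]

    from scipy.spatial import cKDTree

    btree = cKDTree(geom.bfc)

    def classify_exit(x: np.ndarray) -> str:
        _, bi = btree.query(x)
        return mesh.patch_names[mesh.bface_patch[bi]]

    paths, exits = [], []
    step = 0.6 * h
    for s in seeds:
        x = s.copy()
        path = [x.copy()]
        exit_name = ""
        for _ in range(max_steps):
            try:
                u1 = solution.sample_velocity(x[None, :])[0]
            except ValueError:
                exit_name = classify_exit(x)
                break
            sp = np.linalg.norm(u1)
            if sp < 1e-12:
                break
            try:
                u2 = solution.sample_velocity((x + 0.5 * step * u1 / sp)[None, :])[0]
            except ValueError:
                u2 = u1
            sp2 = np.linalg.norm(u2)
            if sp2 < 1e-12:
                break
            x = x + step * u2 / sp2
            path.append(x.copy())
        else:
            exit_name = ""
        paths.append(np.array(path))
        exits.append(exit_name)

    split = _split_fractions(solution, exits)
    return StreamlineSet(paths, exits, split)


def _split_fractions(solution: FlowSolution, exits: list[str]) -> dict[int, tuple[float, float]]:
    tree = solution.mesh.metadata.get("tree_ref")
    if tree is None:
        return {}
    from .geometry import cap_specs

    caps = {c.name: c.segment_index for c in cap_specs(tree)}
    counts: dict[int, list[int]] = {}
    for e in exits:
        if e not in caps or not e.startswith("outlet"):
            continue
        leaf = caps[e]
        chain = tree.leaf_ancestors(leaf)
        for parent, child in zip(chain, chain[1:]):
            kids = tree.segments[parent].children
            side = kids.index(child)
            counts.setdefault(parent, [0, 0])[side] += 1
    out = {}
    for parent, (a, b) in counts.items():
        tot = a + b
        if tot:
            out[parent] = (a / tot, b / tot)
    return out


# --------------------------------------------------------------------------
# Study report
# --------------------------------------------------------------------------


@dataclass
class CaseResult:
    age: str
    phase: str
    solution: FlowSolution
    probe_set: ProbeSet | None = None
    network_drop: float | None = None  # Pa, Poiseuille-network oracle

    def metrics(self) -> dict:
        umax, gen = max_velocity(self.solution)
        dp = pressure_drop(self.solution)
        wall = wall_shear_stress(self.solution)
        row = {
            "age": self.age,
            "phase": self.phase,
            "max_velocity_ms": umax,
            "max_velocity_generation": gen,
            "pressure_drop_Pa": dp,
            "max_wall_pressure_Pa": max_wall_pressure(self.solution),
            "max_wss_Pa": wall.max_wss,
            "wss_q999_Pa": wall.wss_quantile(0.999),
            "converged": self.solution.converged,
            "iterations": self.solution.iteration_count,
            "cells": self.solution.mesh.n_cells,
            "mass_imbalance": self.solution.global_mass_imbalance,
        }
        if self.network_drop is not None:
            row["network_drop_Pa"] = self.network_drop
        return row


@dataclass
class StudyReport:
    table: pd.DataFrame
    sections: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    monotonicity: dict[str, bool] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_AGE_ORDER = {"infant": 0, "child": 1, "adult": 2}


def build_report(cases: Sequence[CaseResult]) -> StudyReport:
    """Cross-age, cross-phase table with published-value comparison columns."""
    if not cases:
        raise ValueError("no cases to report")
    rows = []
    sections = {}
    for case in cases:
        row = case.metrics()
        ref = REPORTED_VALUES.get((case.age, case.phase))
        if ref:
            for key, col in [
                ("max_velocity", "max_velocity_ms"),
                ("pressure_drop", "pressure_drop_Pa"),
                ("max_wss", "max_wss_Pa"),
            ]:
                row[f"reported_{key}"] = ref[key]
                row[f"rel_diff_{key}"] = (row[col] - ref[key]) / ref[key]
        rows.append(row)
        if case.probe_set is not None:
            sections[(case.age, case.phase)] = section_stats(
                case.solution, case.probe_set
            ).as_frame()
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["phase", "age"],
        key=lambda s: s.map(_AGE_ORDER).fillna(99) if s.name == "age" else s,
    ).reset_index(drop=True)

    mono = {}
    for metric in ["max_velocity_ms", "pressure_drop_Pa", "max_wss_Pa"]:
        for phase in table["phase"].unique():
            sub = table[table["phase"] == phase]
            sub = sub[sub["age"].isin(_AGE_ORDER)]
            if len(sub) == 3:
                vals = sub.sort_values("age", key=lambda s: s.map(_AGE_ORDER))[metric].values
                mono[f"{metric}_decreases_with_age_{phase}"] = bool(
                    vals[0] > vals[1] > vals[2]
                )
    for age in table["age"].unique():
        sub = table[table["age"] == age]
        if {"inspiration", "expiration"} <= set(sub["phase"]):
            pi = sub[sub["phase"] == "inspiration"]["pressure_drop_Pa"].iloc[0]
            pe = sub[sub["phase"] == "expiration"]["pressure_drop_Pa"].iloc[0]
            mono[f"inspiration_drop_exceeds_expiration_{age}"] = bool(pi > pe)
    return StudyReport(table=table, sections=sections, monotonicity=mono)
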