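"""Airway geometry: profiles, centerline trees, surfaces, probes, export."""

import numpy as np
import pytest

from airwaycfd import geometry as G


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------


def test_embedded_dimensions_match_table():
    infant = G.build_profile("infant")
    g6 = infant.generation(6)
    assert (g6.length_mm, g6.diameter_mm) == (3.5, 1.0)
    assert g6.outer_curvature_mm == 1.8
    assert g6.carinal_radius_mm == pytest.approx(0.09)
    adult9 = G.build_profile("adult").generation(9)
    assert (adult9.length_mm, adult9.diameter_mm) == (5.3, 1.5)
    assert adult9.outer_curvature_mm is None and adult9.carinal_radius_mm is None


def test_unknown_profile_rejected():
    with pytest.raises(ValueError):
        G.build_profile("dog")


def test_monotone_scaling_across_ages():
    """For every generation, infant < child < adult in both L and D."""
    infant, child, adult = (G.build_profile(a) for a in ("infant", "child", "adult"))
    for g in (6, 7, 8, 9):
        assert (
            infant.generation(g).length_mm
            < child.generation(g).length_mm
            < adult.generation(g).length_mm
        )
        assert (
            infant.generation(g).diameter_mm
            < child.generation(g).diameter_mm
            < adult.generation(g).diameter_mm
        )


def test_interpolated_profile_anchors_and_midpoint():
    assert G.interpolate_profile(5.0).generation(6).diameter_mm == 1.8
    assert G.interpolate_profile(15.0).generation(6).diameter_mm == pytest.approx(2.3)
    with pytest.raises(ValueError):
        G.interpolate_profile(30.0)


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        G.GenerationDims(6, -1.0, 1.0)
    with pytest.raises(ValueError):  # carinal radius must fit inside the branch
        G.GenerationDims(6, 3.0, 1.0, 1.0, 0.6)


# --------------------------------------------------------------------------
# Centerline tree
# --------------------------------------------------------------------------


@pytest.mark.parametrize("age", ["infant", "child", "adult"])
def test_tree_topology_and_angles(age):
    tree = G.build_centerline_tree(G.build_profile(age))
    assert len(tree.segments) == 15
    assert len(tree.leaves) == 8
    for seg in tree.segments:
        assert len(seg.children) in (0, 2)
        if seg.children:
            d1 = tree.segments[seg.children[0]].direction
            d2 = tree.segments[seg.children[1]].direction
            angle = np.degrees(np.arccos(np.clip(d1 @ d2, -1, 1)))
            assert angle == pytest.approx(70.0, abs=1e-6)
    # planar
    pts = np.array([s.start for s in tree.segments] + [s.end for s in tree.segments])
    assert np.abs(pts[:, 2]).max() < 1e-12


def test_infant_root_to_tip_path_length():
    tree = G.build_centerline_tree(G.build_profile("infant"))
    total = 0.0
    seg = tree.root
    while True:
        total += seg.length
        if not seg.children:
            break
        seg = tree.segments[seg.children[0]]
    assert total == pytest.approx(11.0e-3)


def test_right_daughter_convention():
    tree = G.build_centerline_tree(G.build_profile("infant"))
    right7 = tree.right_segment(7)
    assert right7.generation_index == 7
    assert right7.direction[1] < 0  # "right" deviates toward negative y


# --------------------------------------------------------------------------
# Surface
# --------------------------------------------------------------------------


def test_surface_is_closed_manifold_with_nine_caps(infant_surface):
    tm = infant_surface.as_trimesh()
    assert tm.is_watertight
    assert tm.volume > 0
    caps = [n for n in infant_surface.patch_names if n != "wall"]
    assert caps == ["inlet"] + [f"outlet_{k}" for k in range(1, 9)]
    for name in caps:
        assert infant_surface.patch_area(name) > 0


def test_surface_cap_areas_match_disks(infant_surface, infant_profile):
    d6 = infant_profile.generation(6).diameter_mm * 1e-3
    d9 = infant_profile.generation(9).diameter_mm * 1e-3
    assert infant_surface.patch_area("inlet") == pytest.approx(
        np.pi * (d6 / 2) ** 2, rel=0.02
    )
    for k in range(1, 9):
        assert infant_surface.patch_area(f"outlet_{k}") == pytest.approx(
            np.pi * (d9 / 2) ** 2, rel=0.02
        )


def test_surface_caps_planar_and_axial(infant_surface, infant_tree):
    for cap in G.cap_specs(infant_tree):
        tri = infant_surface.patch_triangles(cap.name)
        verts = infant_surface.vertices[np.unique(tri)]
        offsets = (verts - cap.point) @ cap.outward_normal
        assert np.abs(offsets).max() < 1e-9


@pytest.mark.parametrize("g", [6, 7, 8, 9])
def test_mid_generation_cross_section_area(infant_surface, infant_profile, infant_tree, g):
    """Mid-segment cross sections stay within 2% of the tabulated disk area."""
    tm = infant_surface.as_trimesh()
    seg = infant_tree.of_generation(g)[0]
    sliced = tm.section(plane_origin=seg.midpoint, plane_normal=seg.direction)
    flat, _ = sliced.to_2D()
    d = infant_profile.generation(g).diameter_mm * 1e-3
    ref = np.pi * (d / 2) ** 2
    areas = [p.area for p in flat.polygons_closed if p is not None]
    best = min(areas, key=lambda a: abs(a - ref))
    assert best == pytest.approx(ref, rel=0.02)


def test_surface_mirror_symmetry(infant_surface):
    """Reflection across the bifurcation plane's in-plane axis stays on-surface."""
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(0)
    verts = infant_surface.vertices[np.unique(infant_surface.triangles)]
    pick = rng.choice(len(verts), size=400, replace=False)
    mirrored = verts[pick] * np.array([1.0, -1.0, 1.0])
    # mirrored vertices must land back on (a vertex of) the triangulation
    d_vertex, _ = cKDTree(verts).query(mirrored)
    assert np.max(d_vertex) < infant_surface.metadata["edge_length"]
    # and exactly on the implicit solid boundary, which is symmetric only
    # if the blended union construction is
    d_surface = np.abs(G.tree_signed_distance(infant_surface.tree, mirrored))
    assert np.max(d_surface) < 0.5 * infant_surface.metadata["edge_length"]


def test_tube_surface_lateral_area(tube_surface):
    lateral = tube_surface.patch_area("wall")
    assert lateral == pytest.approx(np.pi * 0.002 * 0.01, rel=0.01)
    assert tube_surface.as_trimesh().is_watertight


def test_bad_resolution_rejected(infant_tree):
    with pytest.raises(ValueError):
        G.build_surface(infant_tree, resolution=0.0)


# --------------------------------------------------------------------------
# Probes
# --------------------------------------------------------------------------


def test_probe_set_counts_and_containment(infant_tree):
    probes = G.make_probe_set(infant_tree)
    assert len(probes.mid_sections) == 15
    assert probes.path_points.shape == (5, 3)
    seg = infant_tree.segments[probes.path_segment_index]
    assert seg.generation_index == 7
    rel = probes.path_points - seg.start
    t = rel @ seg.direction
    radial = np.linalg.norm(rel - t[:, None] * seg.direction, axis=1)
    assert np.all((t > 0) & (t < seg.length))  # interior, endpoints excluded
    assert np.all(radial < seg.radius)
    # G6 mid-section passes through the root-axis midpoint
    g6 = next(p for p in probes.mid_sections if p.generation_index == 6)
    assert np.allclose(g6.center, infant_tree.root.midpoint)


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------


def test_stl_roundtrip_and_orientation(tmp_path, infant_surface):
    import trimesh

    path = tmp_path / "infant.stl"
    G.export_surface(infant_surface, path, "stl")
    loaded = trimesh.load(path)
    assert len(loaded.faces) == len(infant_surface.triangles)
    assert loaded.volume > 0  # outward-facing normals
    sidecar = path.with_suffix(".stl.json")
    assert sidecar.exists()


def test_vtk_polydata_export(tmp_path, infant_surface):
    path = tmp_path / "infant.vtk"
    G.export_surface(infant_surface, path, "vtk")
    text = path.read_text()
    assert f"POINTS {len(infant_surface.vertices)} double" in text
    assert "POLYGONS" in text and "SCALARS patch" in text


def test_unsupported_export_format(tmp_path, infant_surface):
    with pytest.raises(ValueError):
        G.export_surface(infant_surface, tmp_path / "x.obj", "obj")
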