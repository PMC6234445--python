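"""Minimal ASCII writers/readers for unstructured mesh and solution files.

Emits legacy-free, widely readable formats: XML VTU (appended-free ASCII)
for tetrahedral meshes with point/cell data, and Gmsh MSH 2.2 for meshes
with boundary patch tags.  Only the subset needed by this package is
implemented.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtu", "write_msh", "read_msh"]


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind in "iu":
        return " ".join(map(str, a.ravel()))
    return " ".join(f"{x:.9e}" for x in a.ravel())


def write_vtu(
    path: str | Path,
    points: np.ndarray,
    cells: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write a tetrahedral mesh (+ optional fields) as ASCII .vtu."""
    path = Path(path)
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    n_pts, n_cells = len(points), len(cells)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt_array(points),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt_array(cells),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt_array(np.arange(1, n_cells + 1) * cells.shape[1]),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt_array(np.full(n_cells, 10 if cells.shape[1] == 4 else 5, dtype=np.uint8)),
        "</DataArray>",
        "</Cells>",
    ]

    def data_block(tag: str, data: dict[str, np.ndarray]) -> list[str]:
        out = [f"<{tag}>"]
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            dtype = "Float64" if arr.dtype.kind == "f" else "Int64"
            out.append(
                f'<DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append(_fmt_array(arr))
            out.append("</DataArray>")
        out.append(f"</{tag}>")
        return out

    if point_data:
        lines += data_block("PointData", point_data)
    if cell_data:
        lines += data_block("CellData", cell_data)
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_msh(
    path: str | Path,
    points: np.ndarray,
    cells: np.ndarray,
    boundary_faces: np.ndarray | None = None,
    boundary_patch: np.ndarray | None = None,
    patch_names: list[str] | None = None,
) -> Path:
    """Write Gmsh MSH 2.2 ASCII with tets and tagged boundary triangles."""
    path = Path(path)
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    if patch_names:
        lines += ["$PhysicalNames", str(len(patch_names))]
        lines += [f'2 {i + 1} "{name}"' for i, name in enumerate(patch_names)]
        lines += ["$EndPhysicalNames"]
    lines += ["$Nodes", str(len(points))]
    lines += [
        f"{i + 1} {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}" for i, p in enumerate(points)
    ]
    lines += ["$EndNodes", "$Elements"]
    n_bnd = 0 if boundary_faces is None else len(boundary_faces)
    lines.append(str(n_bnd + len(cells)))
    eid = 1
    if boundary_faces is not None:
        for f, p in zip(np.asarray(boundary_faces), np.asarray(boundary_patch)):
            lines.append(f"{eid} 2 2 {p + 1} {p + 1} {f[0] + 1} {f[1] + 1} {f[2] + 1}")
            eid += 1
    for c in cells:
        lines.append(f"{eid} 4 2 0 0 {c[0] + 1} {c[1] + 1} {c[2] + 1} {c[3] + 1}")
        eid += 1
    lines += ["$EndElements"]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_msh(path: str | Path):
    """Read back a MSH 2.2 file written by :func:`write_msh`.

    Returns (points, cells, boundary_faces, boundary_patch, patch_names).
    """
    tokens = Path(path).read_text().splitlines()
    i = 0
    points = cells = None
    bfaces: list[list[int]] = []
    bpatch: list[int] = []
    patch_names: list[str] = []
    while i < len(tokens):
        line = tokens[i].strip()
        if line == "$PhysicalNames":
            n = int(tokens[i + 1])
            for j in range(n):
                parts = tokens[i + 2 + j].split(maxsplit=2)
                patch_names.append(parts[2].strip('"'))
            i += n + 2
        elif line == "$Nodes":
            n = int(tokens[i + 1])
            points = np.array(
                [list(map(float, tokens[i + 2 + j].split()[1:4])) for j in range(n)]
            )
            i += n + 2
        elif line == "$Elements":
            n = int(tokens[i + 1])
            tets = []
            for j in range(n):
                parts = list(map(int, tokens[i + 2 + j].split()))
                etype, ntags = parts[1], parts[2]
                nodes = [v - 1 for v in parts[3 + ntags :]]
                if etype == 2:
                    bfaces.append(nodes)
                    bpatch.append(parts[3] - 1)
                elif etype == 4:
                    tets.append(nodes)
            cells = np.array(tets, dtype=np.int64)
            i += n + 2
        else:
            i += 1
    return (
        points,
        cells,
        np.array(bfaces, dtype=np.int64) if bfaces else None,
        np.array(bpatch, dtype=int) if bpatch else None,
        patch_names,
    )
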