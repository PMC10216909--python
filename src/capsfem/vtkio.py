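"""Legacy-ASCII VTK unstructured-grid I/O for labelled triangle meshes.

Meshes are written as triangle-only ``DATASET UNSTRUCTURED_GRID`` files with
the region label (integer-coded; the code order is recorded on the VTK title
line) and wall thickness as cell data, and each named node set as a 0/1
point-data array ``set_<name>``.  Solved states are exported with nodal
displacement vectors and per-element maximum principal strain, readable by
ParaView and friends.
"""

from __future__ import annotations

import numpy as np

from .geometry import CapsuleMesh
from .solver import StrainField

__all__ = ["write_mesh", "read_mesh", "write_field"]

_TITLE_PREFIX = "capsfem mesh regions:"


def write_mesh(path, mesh: CapsuleMesh) -> None:
    """Write a labelled capsule mesh as legacy ASCII VTK."""
    mesh.validate()
    region_names = mesh.regions()
    code = {r: i for i, r in enumerate(region_names)}
    lines = [
        "# vtk DataFile Version 3.0",
        _TITLE_PREFIX + ",".join(region_names),
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(repr(float(v)) for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    lines += ["3 " + " ".join(str(int(i)) for i in t) for t in mesh.triangles]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["5"] * mesh.n_elements
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("FIELD celldata 2")
    lines.append(f"region 1 {mesh.n_elements} int")
    lines += [str(code[r]) for r in mesh.region_of_element]
    lines.append(f"thickness 1 {mesh.n_elements} double")
    lines += [repr(float(t)) for t in mesh.thickness_of_element]
    if mesh.node_sets:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append(f"FIELD pointdata {len(mesh.node_sets)}")
        for name, idx in mesh.node_sets.items():
            flag = np.zeros(mesh.n_nodes, dtype=int)
            flag[idx] = 1
            lines.append(f"set_{name} 1 {mesh.n_nodes} int")
            lines += [str(v) for v in flag]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mesh(path) -> CapsuleMesh:
    """Read a mesh written by :func:`write_mesh` (or equivalent).

    Only triangle cells are accepted; the ``region`` and ``thickness`` cell
    arrays are required and their absence is reported explicitly.
    """
    with open(path, "r") as fh:
        tokens_lines = fh.read().splitlines()
    if len(tokens_lines) < 5:
        raise ValueError(f"{path}: not a legacy VTK file")
    title = tokens_lines[1]
    region_names = (
        title[len(_TITLE_PREFIX):].split(",") if title.startswith(_TITLE_PREFIX) else []
    )
    flat = " ".join(
        ln for ln in tokens_lines[2:] if not ln.startswith("#")
    ).split()
    pos = 0

    def expect(word):
        nonlocal pos
        if pos >= len(flat) or flat[pos].upper() != word:
            raise ValueError(f"{path}: expected {word} at token {pos}")
        pos += 1

    def take(n, cast):
        nonlocal pos
        out = [cast(t) for t in flat[pos : pos + n]]
        if len(out) != n:
            raise ValueError(f"{path}: truncated file")
        pos += n
        return out

    expect("ASCII")
    expect("DATASET")
    expect("UNSTRUCTURED_GRID")
    expect("POINTS")
    n_pts = int(flat[pos]); pos += 2  # count + dtype
    if n_pts == 0:
        raise ValueError(f"{path}: empty mesh (no points)")
    nodes = np.array(take(3 * n_pts, float)).reshape(n_pts, 3)
    expect("CELLS")
    n_cells = int(flat[pos]); pos += 2  # count + total size
    if n_cells == 0:
        raise ValueError(f"{path}: empty mesh (no cells)")
    tris = []
    for _ in range(n_cells):
        k = int(flat[pos]); pos += 1
        conn = take(k, int)
        if k != 3:
            raise ValueError(
                f"{path}: only triangle cells are supported, found a {k}-node cell"
            )
        tris.append(conn)
    triangles = np.array(tris, dtype=np.int64)
    expect("CELL_TYPES")
    n_types = int(flat[pos]); pos += 1
    types = take(n_types, int)
    if any(t != 5 for t in types):
        raise ValueError(f"{path}: non-triangle VTK cell types present")

    region_codes = None
    thickness = None
    node_sets: dict[str, np.ndarray] = {}
    while pos < len(flat):
        word = flat[pos].upper()
        if word in ("CELL_DATA", "POINT_DATA"):
            count = int(flat[pos + 1]); pos += 2
        elif word == "FIELD":
            n_arrays = int(flat[pos + 2]); pos += 3
            for _ in range(n_arrays):
                name = flat[pos]
                n_comp = int(flat[pos + 1])
                n_tup = int(flat[pos + 2])
                dtype = flat[pos + 3]
                pos += 4
                vals = take(n_comp * n_tup, float if dtype == "double" else int)
                if name == "region":
                    region_codes = np.array(vals, dtype=int)
                elif name == "thickness":
                    thickness = np.array(vals, dtype=float)
                elif name.startswith("set_"):
                    node_sets[name[4:]] = np.flatnonzero(np.array(vals, dtype=int))
        else:
            pos += 1  # skip unknown keywords (SCALARS blocks etc.)
    missing = [k for k, v in (("region", region_codes), ("thickness", thickness)) if v is None]
    if missing:
        raise ValueError(f"{path}: required cell-data arrays absent: {missing}")
    if not region_names:
        raise ValueError(f"{path}: region code table missing from the VTK title line")
    region = np.array([region_names[c] for c in region_codes], dtype=object)
    mesh = CapsuleMesh(nodes, triangles, region, thickness, node_sets)
    mesh.validate()
    return mesh


def write_field(path, mesh: CapsuleMesh, displacements, field: StrainField) -> None:
    """Export a solved step: displacement vectors + max principal strain."""
    u = np.asarray(displacements, dtype=float)
    region_names = mesh.regions()
    code = {r: i for i, r in enumerate(region_names)}
    lines = [
        "# vtk DataFile Version 3.0",
        _TITLE_PREFIX + ",".join(region_names),
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(repr(float(v)) for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    lines += ["3 " + " ".join(str(int(i)) for i in t) for t in mesh.triangles]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["5"] * mesh.n_elements
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("VECTORS displacement double")
    lines += [" ".join(repr(float(v)) for v in p) for p in u]
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("FIELD celldata 3")
    lines.append(f"max_principal_strain 1 {mesh.n_elements} double")
    lines += [repr(float(v)) for v in field.max_principal]
    lines.append(f"region 1 {mesh.n_elements} int")
    lines += [str(code[r]) for r in mesh.region_of_element]
    lines.append(f"thickness 1 {mesh.n_elements} double")
    lines += [repr(float(t)) for t in mesh.thickness_of_element]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
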