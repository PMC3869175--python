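"""EX (exnode/exelem) and legacy-VTK serialization of Hermite meshes.

The EX dialect written here is the minimal cmGui field template for a
3-component rectangular-cartesian coordinate field with a tricubic Hermite
basis and unit scale factors.  Per node, each coordinate component lists
eight values in the cmGui derivative order::

    value, d/ds1, d/ds2, d2/ds1ds2, d/ds3, d2/ds1ds3, d2/ds2ds3, d3/ds1ds2ds3

Floats are emitted with 17 significant digits so that
``read_ex(write_ex(mesh))`` reproduces every DOF bit-exactly.  EX files in
the wild vary by vendor; the reader only guarantees support for files
written by :func:`write_ex`.
"""

from __future__ import annotations

import os
from typing import List, Tuple

import numpy as np

from .hermite import HermiteMesh, evaluate_element

__all__ = ["write_ex", "read_ex", "write_vtk"]

# cmGui derivative order -> (d1, d2, d3) DOF indices
_CMGUI_DOF_ORDER = [
    (0, 0, 0),
    (1, 0, 0),
    (0, 1, 0),
    (1, 1, 0),
    (0, 0, 1),
    (1, 0, 1),
    (0, 1, 1),
    (1, 1, 1),
]

_NODE_HEADER = """ Group name: cardiomesh
 #Fields=1
 1) coordinates, coordinate, rectangular cartesian, #Components=3
   x.  Value index= 1, #Derivatives= 7 (d/ds1,d/ds2,d2/ds1ds2,d/ds3,d2/ds1ds3,d2/ds2ds3,d3/ds1ds2ds3)
   y.  Value index= 9, #Derivatives= 7 (d/ds1,d/ds2,d2/ds1ds2,d/ds3,d2/ds1ds3,d2/ds2ds3,d3/ds1ds2ds3)
   z.  Value index=17, #Derivatives= 7 (d/ds1,d/ds2,d2/ds1ds2,d/ds3,d2/ds1ds3,d2/ds2ds3,d3/ds1ds2ds3)
"""

_ELEM_HEADER = """ Group name: cardiomesh
 Shape.  Dimension=3
 #Scale factor sets= 1
   c.Hermite*c.Hermite*c.Hermite, #Scale factors=64
 #Nodes=           8
 #Fields=1
 1) coordinates, coordinate, rectangular cartesian, #Components=3
   x.  c.Hermite*c.Hermite*c.Hermite, no modify, standard node based.
     #Nodes= 8
"""


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def write_ex(mesh: HermiteMesh, path: str) -> Tuple[str, str]:
    """Write ``<path>.exnode`` and ``<path>.exelem``; returns both paths.

    ``path`` is a file stem (an existing ``.exnode``/``.exelem`` suffix is
    stripped).
    """
    stem, ext = os.path.splitext(path)
    if ext not in (".exnode", ".exelem"):
        stem = path
    node_path, elem_path = stem + ".exnode", stem + ".exelem"

    lines: List[str] = [_NODE_HEADER.rstrip("\n")]
    for i in range(mesh.n_nodes):
        lines.append(f" Node: {i + 1}")
        for c in range(3):
            vals = [mesh.node_dofs[i, d1, d2, d3, c] for (d1, d2, d3) in _CMGUI_DOF_ORDER]
            lines.append("   " + "  ".join(_fmt(v) for v in vals))
    with open(node_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    lines = [_ELEM_HEADER.rstrip("\n")]
    for e in range(mesh.n_elements):
        lines.append(f" Element: {e + 1} 0 0")
        lines.append("   Nodes:")
        lines.append("     " + " ".join(str(n + 1) for n in mesh.elements[e]))
    with open(elem_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return node_path, elem_path


def read_ex(path: str) -> HermiteMesh:
    """Read a mesh written by :func:`write_ex` from a file stem.

    Topology metadata (face sets, regions, ties) is not stored in EX files;
    the returned mesh carries nodes, DOFs and connectivity only.
    """
    stem, ext = os.path.splitext(path)
    if ext not in (".exnode", ".exelem"):
        stem = path
    node_path, elem_path = stem + ".exnode", stem + ".exelem"

    node_blocks: List[np.ndarray] = []
    with open(node_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if lines[i].strip().startswith("Node:"):
            vals = []
            for c in range(3):
                vals.append([float(t) for t in lines[i + 1 + c].split()])
            dofs = np.zeros((2, 2, 2, 3))
            for c in range(3):
                for k, (d1, d2, d3) in enumerate(_CMGUI_DOF_ORDER):
                    dofs[d1, d2, d3, c] = vals[c][k]
            node_blocks.append(dofs)
            i += 4
        else:
            i += 1
    if not node_blocks:
        raise ValueError(f"no nodes found in {node_path}")

    elems: List[List[int]] = []
    with open(elem_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if lines[i].strip().startswith("Element:"):
            assert lines[i + 1].strip().startswith("Nodes")
            elems.append([int(t) - 1 for t in lines[i + 2].split()])
            i += 3
        else:
            i += 1
    return HermiteMesh(np.stack(node_blocks), np.asarray(elems, dtype=int))


# VTK corner order for VTK_HEXAHEDRON relative to (i1, i2, i3) offsets
_VTK_CORNERS = [
    (0, 0, 0),
    (1, 0, 0),
    (1, 1, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 0, 1),
    (1, 1, 1),
    (0, 1, 1),
]


def write_vtk(mesh: HermiteMesh, path: str, subdivision: int = 3) -> str:
    """Write a legacy-ASCII VTK unstructured grid of subdivided hexahedra.

    Each Hermite element is sampled on a ``(subdivision+1)^3`` lattice and
    emitted as ``subdivision^3`` linear hexahedral cells (visualization
    only; points at element interfaces are duplicated).
    """
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    m = subdivision
    t = np.linspace(0.0, 1.0, m + 1)
    lattice = np.stack(np.meshgrid(t, t, t, indexing="ij"), axis=-1).reshape(-1, 3)

    points: List[np.ndarray] = []
    cells: List[List[int]] = []
    stride = (m + 1) ** 3

    def lid(i1: int, i2: int, i3: int) -> int:
        return (i1 * (m + 1) + i2) * (m + 1) + i3

    for e in range(mesh.n_elements):
        base = e * stride
        points.append(evaluate_element(mesh, e, lattice))
        for i1 in range(m):
            for i2 in range(m):
                for i3 in range(m):
                    cells.append(
                        [base + lid(i1 + a, i2 + b, i3 + c) for (a, b, c) in _VTK_CORNERS]
                    )
    pts = np.concatenate(points, axis=0)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncardiomesh surface-subdivided mesh\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {len(cells)} {9 * len(cells)}\n")
        for c in cells:
            fh.write("8 " + " ".join(map(str, c)) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.write("\n".join(["12"] * len(cells)) + "\n")
    return path
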