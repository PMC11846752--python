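"""Mesh and pose serialisation.

Meshes are written in the legacy ASCII VTK unstructured-grid format
(readable by ParaView and most mesh tools); node sets and material labels
travel as point/cell data arrays so a written mesh round-trips losslessly.
Poses are parsed from plain ``dx,dy[,dz],alpha[,beta],gamma`` text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np

from .geometry import SimplexMesh
from .morphing import ImplantPose

__all__ = ["save_mesh", "load_mesh", "parse_pose"]

_VTK_CELL = {2: 5, 3: 10}  # triangle, tetrahedron
_SET_CODE = {"fixed_boundary": 1, "implant": 2, "interior": 0}


def save_mesh(mesh: SimplexMesh, path, point_data: Dict[str, np.ndarray] | None = None,
              cell_data: Dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh (plus optional fields) as legacy ASCII VTK."""
    path = Path(path)
    d = mesh.dim
    n, m = mesh.n_nodes, mesh.n_elements
    pts = mesh.nodes if d == 3 else np.column_stack(
        [mesh.nodes, np.zeros(n)])
    lines = [
        "# vtk DataFile Version 3.0",
        "bonerom mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{v:.17g}" for v in p) for p in pts]
    nn = d + 1
    lines.append(f"CELLS {m} {m * (nn + 1)}")
    lines += [f"{nn} " + " ".join(map(str, e)) for e in mesh.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += [str(_VTK_CELL[d])] * m

    node_set_code = np.zeros(n, dtype=int)
    for name, idx in mesh.node_sets.items():
        node_set_code[idx] = _SET_CODE[name]
    pdata = {"node_set": node_set_code}
    pdata.update(point_data or {})
    lines.append(f"POINT_DATA {n}")
    for name, arr in pdata.items():
        arr = np.asarray(arr)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.17g}" for v in arr.astype(float)]

    material_code = (mesh.element_material == "implant").astype(int)
    cdata = {"material": material_code}
    cdata.update(cell_data or {})
    lines.append(f"CELL_DATA {m}")
    for name, arr in cdata.items():
        arr = np.asarray(arr)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.17g}" for v in arr.astype(float)]
    path.write_text("\n".join(lines) + "\n")


def load_mesh(path):
    """Read a mesh written by :func:`save_mesh`.

    Returns ``(mesh, point_data, cell_data)``; the ``node_set`` and
    ``material`` arrays are decoded back into the mesh structure.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(range(len(tokens)))
    i = 0

    def seek(prefix):
        nonlocal i
        while i < len(tokens) and not tokens[i].startswith(prefix):
            i += 1
        if i >= len(tokens):
            raise ValueError(f"malformed VTK file: missing {prefix}")
        return tokens[i]

    header = seek("POINTS")
    n = int(header.split()[1])
    pts = np.array([[float(x) for x in tokens[i + 1 + k].split()]
                    for k in range(n)])
    i += n
    header = seek("CELLS")
    m = int(header.split()[1])
    cells = np.array([[int(x) for x in tokens[i + 1 + k].split()[1:]]
                      for k in range(m)], dtype=np.int64)
    i += m
    header = seek("CELL_TYPES")
    ctype = int(tokens[i + 1])
    dim = 2 if ctype == _VTK_CELL[2] else 3
    nodes = pts[:, :dim]

    def read_scalars(count):
        # sequential: consume SCALARS blocks until a non-SCALARS line
        nonlocal i
        data = {}
        while i < len(tokens) and tokens[i].startswith("SCALARS"):
            name = tokens[i].split()[1]
            i += 2  # skip the LOOKUP_TABLE line
            data[name] = np.array(
                [float(tokens[i + k]) for k in range(count)])
            i += count
        return data

    seek("POINT_DATA")
    i += 1
    point_data = read_scalars(n)
    seek("CELL_DATA")
    i += 1
    cell_data = read_scalars(m)

    codes = point_data.pop("node_set").astype(int)
    inv = {v: k for k, v in _SET_CODE.items()}
    node_sets = {inv[c]: np.flatnonzero(codes == c).astype(np.int64)
                 for c in sorted(inv)}
    material = np.where(cell_data.pop("material").astype(int) == 1,
                        "implant", "bone").astype("U7")
    mesh = SimplexMesh(nodes=nodes, elements=cells, node_sets=node_sets,
                       element_material=material)
    return mesh, point_data, cell_data


def parse_pose(text: str) -> ImplantPose:
    """Parse ``dx,dy[,dz],alpha[,beta],gamma`` (3 or 6 comma-separated values)."""
    vals = [float(v) for v in text.replace(";", ",").split(",") if v.strip()]
    if len(vals) == 3:
        return ImplantPose(dx=vals[0], dy=vals[1], gamma=vals[2])
    if len(vals) == 6:
        return ImplantPose(*vals)
    raise ValueError("pose must have 3 (2D) or 6 (3D) comma-separated values")
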