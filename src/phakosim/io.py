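"""Mesh and result export, and YAML run configuration.

Writers emit ASCII VTK XML (.vtu) unstructured grids and Gmsh MSH 2.2
meshes with named physical groups, so runs can be inspected in ParaView or
Gmsh. Only the subset of each format needed for this package is produced;
``read_msh`` parses files written by :func:`write_msh` (round-trip).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .fem import BoundaryProtocol
from .geometry import GeometryParams, LensShapeParams
from .mesh import FEMesh

__all__ = ["write_vtu", "write_msh", "read_msh", "load_config", "save_config"]

_VTK_TET = 10
_VTK_TRI = 5


def _collect_cells(mesh: FEMesh):
    """All cells as (connectivity list, vtk type, group name) triples."""
    cells = [(mesh.tets, _VTK_TET, "nucleus+cortex")]
    cells.append((mesh.capsule_tris, _VTK_TRI, "capsule"))
    for s, tris in mesh.zonule_tris.items():
        cells.append((tris, _VTK_TRI, s))
    return cells


def write_vtu(
    mesh: FEMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the full mesh (solids + membranes) as an ASCII .vtu file.

    ``point_data`` arrays are (n_nodes,) or (n_nodes, 3); ``cell_data``
    arrays must match the global cell count (tets, capsule, then zonules) —
    a per-cell integer ``region`` field is always included.
    """
    path = Path(path)
    cells = _collect_cells(mesh)
    conn = np.concatenate([c.ravel() for c, _, _ in cells])
    sizes = np.concatenate([[c.shape[1]] * len(c) for c, _, _ in cells])
    offsets = np.cumsum(sizes)
    types = np.concatenate([[t] * len(c) for c, t, _ in cells])
    region = np.concatenate([[i] * len(c) for i, (c, _, _) in enumerate(cells)])

    def arr(a, fmt="%.9g"):
        return "\n".join(fmt % v if np.ndim(v) == 0 else " ".join(fmt % x for x in v) for v in a)

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{len(types)}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(mesh.nodes),
        "</DataArray>",
        "</Points>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, data in point_data.items():
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            lines += [
                f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">',
                arr(data),
                "</DataArray>",
            ]
        lines.append("</PointData>")
    lines.append("<CellData>")
    lines += [
        '<DataArray type="Int32" Name="region" format="ascii">',
        arr(region, "%d"),
        "</DataArray>",
    ]
    if cell_data:
        for name, data in cell_data.items():
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            lines += [
                f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">',
                arr(data),
                "</DataArray>",
            ]
    lines.append("</CellData>")
    lines += [
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(conn, "%d"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(offsets, "%d"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(types, "%d"),
        "</DataArray>",
        "</Cells>",
        "</Piece>",
        "</UnstructuredGrid>",
        "</VTKFile>",
    ]
    path.write_text("\n".join(lines))
    return path


def write_msh(mesh: FEMesh, path: str | Path) -> Path:
    """Write the mesh in Gmsh MSH 2.2 ASCII with named physical groups."""
    path = Path(path)
    cells = _collect_cells(mesh)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames", str(len(cells))]
    for i, (c, t, name) in enumerate(cells):
        dim = 3 if t == _VTK_TET else 2
        lines.append(f'{dim} {i + 1} "{name}"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.9g} {y:.9g} {z:.9g}")
    lines += ["$EndNodes", "$Elements", str(sum(len(c) for c, _, _ in cells))]
    eid = 1
    for i, (c, t, _) in enumerate(cells):
        etype = 4 if t == _VTK_TET else 2  # gmsh: 4 = tet4, 2 = tri3
        for row in c:
            nodes = " ".join(str(n + 1) for n in row)
            lines.append(f"{eid} {etype} 2 {i + 1} {i + 1} {nodes}")
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines))
    return path


def read_msh(path: str | Path):
    """Read a MSH 2.2 file written by :func:`write_msh`.

    Returns (nodes, {group_name: (connectivity, dim)}).
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)
    names: dict[int, tuple[str, int]] = {}
    nodes = None
    groups: dict[str, list[list[int]]] = {}
    dims: dict[str, int] = {}
    for line in it:
        if line == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                dim, tag, name = next(it).split(maxsplit=2)
                names[int(tag)] = (name.strip('"'), int(dim))
            next(it)
        elif line == "$Nodes":
            n = int(next(it))
            nodes = np.empty((n, 3))
            for k in range(n):
                parts = next(it).split()
                nodes[int(parts[0]) - 1] = [float(v) for v in parts[1:4]]
            next(it)
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                ntags = int(parts[2])
                phys = int(parts[3])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                name, dim = names[phys]
                groups.setdefault(name, []).append(conn)
                dims[name] = dim
            next(it)
    out = {name: (np.asarray(conn, dtype=np.int64), dims[name]) for name, conn in groups.items()}
    return nodes, out


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def save_config(path: str | Path, shape: LensShapeParams, params: GeometryParams, protocol: BoundaryProtocol) -> None:
    from dataclasses import asdict

    payload = {
        "shape": asdict(shape),
        "geometry": asdict(params),
        "protocol": asdict(protocol),
    }
    Path(path).write_text(yaml.safe_dump(payload))


def load_config(path: str | Path):
    """Load (shape, geometry, protocol) from YAML.

    The geometry section accepts either explicit fields or variant names
    under keys ``oval``/``band`` (Tables of the oval and band models).
    """
    payload = yaml.safe_load(Path(path).read_text())
    shape = LensShapeParams(**payload.get("shape", {}))
    geo = dict(payload.get("geometry", {}))
    oval = geo.pop("oval", None)
    band = geo.pop("band", None)
    if oval or band:
        params = GeometryParams.from_variants(oval or "Initial", band or "Ring", **geo)
    else:
        params = GeometryParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in geo.items()})
    proto = payload.get("protocol", {})
    if "gravity_direction" in proto:
        proto["gravity_direction"] = tuple(proto["gravity_direction"])
    protocol = BoundaryProtocol(**proto)
    return shape, params, protocol
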