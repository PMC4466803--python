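"""Mesh and solution-field file I/O.

ASCII VTU is the canonical on-disk format: node coordinates at full
double precision, materials and element regions as cell-data arrays,
node sets as point-data indicator arrays, so a write/read round trip
preserves everything exactly.  Gmsh v2.2 ASCII is supported with the
same fidelity (sets travel as $NodeData/$ElementData blocks).  The outer
surface can be exported as STL for visualisation.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .beak_geometry import TetMesh, boundary_faces

__all__ = ["write_vtu", "read_vtu", "write_gmsh", "read_gmsh",
           "write_surface_stl", "write_solution_vtu"]

_MAT_CODE = {"bone": 1, "keratin": 2}
_MAT_NAME = {v: k for k, v in _MAT_CODE.items()}

_NSET_PREFIX = "nset_"
_ESET_PREFIX = "eset_"


def _fmt(a: np.ndarray) -> str:
    if np.issubdtype(a.dtype, np.integer):
        return " ".join(str(int(v)) for v in a.ravel())
    return " ".join(repr(float(v)) for v in a.ravel())


def write_vtu(mesh: TetMesh, path) -> None:
    """Write a mesh (with all named sets) as ASCII VTU."""
    n, m = mesh.n_nodes, mesh.n_tets
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n),
                          NumberOfCells=str(m))

    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = _fmt(mesh.nodes)

    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64",
                         Name="connectivity", format="ascii")
    conn.text = _fmt(mesh.tets)
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = _fmt(4 * (np.arange(m) + 1))
    typ = ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                        format="ascii")
    typ.text = _fmt(np.full(m, 10, dtype=np.uint8))   # VTK_TETRA

    cdata = ET.SubElement(piece, "CellData")
    matarr = ET.SubElement(cdata, "DataArray", type="Int32", Name="material",
                           format="ascii")
    matarr.text = _fmt(np.array([_MAT_CODE[x] for x in mesh.material]))
    for name in sorted(mesh.element_regions):
        flag = np.zeros(m, dtype=np.int32)
        flag[mesh.element_regions[name]] = 1
        arr = ET.SubElement(cdata, "DataArray", type="Int32",
                            Name=_ESET_PREFIX + name, format="ascii")
        arr.text = _fmt(flag)

    pdata = ET.SubElement(piece, "PointData")
    for name in sorted(mesh.node_sets):
        flag = np.zeros(n, dtype=np.int32)
        flag[mesh.node_sets[name]] = 1
        arr = ET.SubElement(pdata, "DataArray", type="Int32",
                            Name=_NSET_PREFIX + name, format="ascii")
        arr.text = _fmt(flag)

    meta = ET.SubElement(pdata, "DataArray", type="Float64",
                         Name="meta_length", format="ascii")
    meta.text = repr(float(mesh.metadata.get("length", 0.0)))

    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_vtu(path) -> TetMesh:
    """Read a mesh written by :func:`write_vtu`."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    nodes = np.fromstring(piece.find("Points/DataArray").text, sep=" ")
    nodes = nodes.reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.iter("DataArray")
              if da.get("Name")}
    tets = np.fromstring(arrays["connectivity"].text, dtype=np.int64,
                         sep=" ").reshape(-1, 4)
    mat_codes = np.fromstring(arrays["material"].text, dtype=np.int64, sep=" ")
    material = np.array([_MAT_NAME[c] for c in mat_codes])
    node_sets, regions, meta = {}, {}, {}
    for name, da in arrays.items():
        if name.startswith(_NSET_PREFIX):
            flag = np.fromstring(da.text, dtype=np.int64, sep=" ")
            node_sets[name[len(_NSET_PREFIX):]] = np.flatnonzero(flag)
        elif name.startswith(_ESET_PREFIX):
            flag = np.fromstring(da.text, dtype=np.int64, sep=" ")
            regions[name[len(_ESET_PREFIX):]] = np.flatnonzero(flag)
        elif name == "meta_length":
            meta["length"] = float(da.text)
    return TetMesh(nodes=nodes, tets=tets, material=material,
                   node_sets=node_sets, element_regions=regions,
                   metadata=meta)


def write_gmsh(mesh: TetMesh, path) -> None:
    """Write a mesh as Gmsh v2.2 ASCII (.msh).

    Materials become physical volume tags; node sets and element regions
    travel as $NodeData / $ElementData indicator fields so nothing is
    lost on a round trip.
    """
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", "2",
              f'3 {_MAT_CODE["bone"]} "bone"',
              f'3 {_MAT_CODE["keratin"]} "keratin"',
              "$EndPhysicalNames"]
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_tets))
    for e, (tet, lab) in enumerate(zip(mesh.tets, mesh.material), start=1):
        tag = _MAT_CODE[lab]
        a, b, c, d = (int(v) + 1 for v in tet)
        lines.append(f"{e} 4 2 {tag} {tag} {a} {b} {c} {d}")
    lines.append("$EndElements")

    def data_block(kind: str, name: str, size: int, idx: np.ndarray) -> None:
        flag = np.zeros(size, dtype=int)
        flag[idx] = 1
        lines.append(f"${kind}")
        lines.extend(["1", f'"{name}"', "1", "0.0", "3", "0", "1", str(size)])
        for i, v in enumerate(flag, start=1):
            lines.append(f"{i} {v}")
        lines.append(f"$End{kind}")

    for name in sorted(mesh.node_sets):
        data_block("NodeData", _NSET_PREFIX + name, mesh.n_nodes,
                   mesh.node_sets[name])
    for name in sorted(mesh.element_regions):
        data_block("ElementData", _ESET_PREFIX + name, mesh.n_tets,
                   mesh.element_regions[name])
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmsh(path) -> TetMesh:
    """Read a mesh written by :func:`write_gmsh`."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes, tets, mats = None, [], []
    node_sets, regions = {}, {}
    for line in it:
        if line == "$Nodes":
            count = int(next(it))
            nodes = np.empty((count, 3))
            for _ in range(count):
                parts = next(it).split()
                nodes[int(parts[0]) - 1] = [float(p) for p in parts[1:4]]
        elif line == "$Elements":
            count = int(next(it))
            for _ in range(count):
                parts = next(it).split()
                if parts[1] != "4":
                    continue
                ntags = int(parts[2])
                mats.append(_MAT_NAME[int(parts[3])])
                conn = [int(p) - 1 for p in parts[3 + ntags:]]
                tets.append(conn)
        elif line in ("$NodeData", "$ElementData"):
            kind = line[1:]
            n_str = int(next(it))
            names = [next(it).strip('"') for _ in range(n_str)]
            n_real = int(next(it))
            for _ in range(n_real):
                next(it)
            n_int = int(next(it))
            ints = [int(next(it)) for _ in range(n_int)]
            size = ints[-1]
            flag = np.zeros(size, dtype=int)
            for _ in range(size):
                i, v = next(it).split()
                flag[int(i) - 1] = int(v)
            name = names[0]
            if kind == "NodeData" and name.startswith(_NSET_PREFIX):
                node_sets[name[len(_NSET_PREFIX):]] = np.flatnonzero(flag)
            elif kind == "ElementData" and name.startswith(_ESET_PREFIX):
                regions[name[len(_ESET_PREFIX):]] = np.flatnonzero(flag)
    return TetMesh(nodes=nodes, tets=np.array(tets, dtype=np.int64),
                   material=np.array(mats), node_sets=node_sets,
                   element_regions=regions, metadata={})


def write_surface_stl(mesh: TetMesh, path) -> None:
    """Export the outer surface triangulation as STL (via trimesh)."""
    import trimesh

    faces = boundary_faces(mesh)
    if "outer_surface" in mesh.node_sets:
        on = np.zeros(mesh.n_nodes, dtype=bool)
        on[mesh.node_sets["outer_surface"]] = True
        faces = faces[on[faces].all(axis=1)]
    surf = trimesh.Trimesh(vertices=mesh.nodes, faces=faces, process=False)
    surf.export(path)


def write_solution_vtu(mesh: TetMesh, solution, path) -> None:
    """Write displacements, stresses and von Mises values as ASCII VTU."""
    n, m = mesh.n_nodes, mesh.n_tets
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n),
                          NumberOfCells=str(m))
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = _fmt(mesh.nodes)
    cells = ET.SubElement(piece, "Cells")
    for name, arr, typ in (
            ("connectivity", mesh.tets, "Int64"),
            ("offsets", 4 * (np.arange(m) + 1), "Int64"),
            ("types", np.full(m, 10, dtype=np.uint8), "UInt8")):
        d = ET.SubElement(cells, "DataArray", type=typ, Name=name,
                          format="ascii")
        d.text = _fmt(np.asarray(arr))
    pdata = ET.SubElement(piece, "PointData")
    for name, arr in (("displacement", solution.displacement),
                      ("reaction", solution.reactions)):
        d = ET.SubElement(pdata, "DataArray", type="Float64", Name=name,
                          NumberOfComponents="3", format="ascii")
        d.text = _fmt(arr)
    cdata = ET.SubElement(piece, "CellData")
    d = ET.SubElement(cdata, "DataArray", type="Float64", Name="stress",
                      NumberOfComponents="6", format="ascii")
    d.text = _fmt(solution.stress)
    d = ET.SubElement(cdata, "DataArray", type="Float64", Name="von_mises",
                      format="ascii")
    d.text = _fmt(solution.von_mises)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
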