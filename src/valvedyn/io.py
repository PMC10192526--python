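"""Plain-text mesh and field I/O: VTU (XML), Abaqus/CalculiX INP, Gmsh MSH 4.1.

Only the quadratic-tetrahedron subset needed by this package is supported.
VTK cell type 24 (quadratic tetra) shares the C3D10 node ordering.  Gmsh's
10-node tetrahedron (type 11) differs from Abaqus in one midside slot: Gmsh
stores edge (0,2) in slot 9 and (2,3) in slot 8 relative to our ordering.
"""

from __future__ import annotations

import numpy as np

from .geometry import LeafletMesh, LEAFLET_NAMES

# our (Abaqus C3D10) midside order: (01),(12),(02),(03),(13),(23)
_GMSH_FROM_ABQ = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]
_ABQ_FROM_GMSH = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]


def write_vtu(path, mesh: LeafletMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh (and optional fields) as an ASCII .vtu file."""
    n, e = mesh.n_nodes, mesh.n_elements
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{n}" NumberOfCells="{e}">',
             '<Points>',
             '<DataArray type="Float64" NumberOfComponents="3" format="ascii">']
    lines.extend(" ".join(f"{v:.10g}" for v in row) for row in mesh.nodes)
    lines += ['</DataArray>', '</Points>', '<Cells>',
              '<DataArray type="Int64" Name="connectivity" format="ascii">']
    lines.extend(" ".join(map(str, row)) for row in mesh.elements)
    lines += ['</DataArray>',
              '<DataArray type="Int64" Name="offsets" format="ascii">',
              " ".join(str(10 * (i + 1)) for i in range(e)),
              '</DataArray>',
              '<DataArray type="UInt8" Name="types" format="ascii">',
              " ".join(["24"] * e),
              '</DataArray>', '</Cells>']

    def _field_block(name, arr):
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        out = [f'<DataArray type="Float64" Name="{name}" '
               f'NumberOfComponents="{ncomp}" format="ascii">']
        if arr.ndim == 1:
            out.extend(f"{v:.10g}" for v in arr)
        else:
            out.extend(" ".join(f"{v:.10g}" for v in row) for row in arr)
        out.append('</DataArray>')
        return out

    lines.append('<PointData>')
    for name, arr in (point_data or {}).items():
        lines += _field_block(name, arr)
    lines.append('</PointData>')
    lines.append('<CellData>')
    cd = {"leaflet": mesh.leaflet_id.astype(float)}
    cd.update(cell_data or {})
    for name, arr in cd.items():
        lines += _field_block(name, arr)
    lines.append('</CellData>')
    lines += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_inp(path, mesh: LeafletMesh, heading: str = "valvedyn leaflets") -> None:
    """Export C3D10 elements with FIXED node set and per-leaflet surface sets."""
    out = [f"*HEADING\n{heading}", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")
    for li, name in enumerate(LEAFLET_NAMES):
        sel = np.where(mesh.leaflet_id == li)[0]
        if not len(sel):
            continue
        out.append(f"*ELEMENT, TYPE=C3D10, ELSET={name}")
        for e in sel:
            conn = ", ".join(str(v + 1) for v in mesh.elements[e])
            out.append(f"{e + 1}, {conn}")
    out.append("*NSET, NSET=FIXED")
    ids = mesh.fixed_nodes + 1
    for k in range(0, len(ids), 12):
        out.append(", ".join(map(str, ids[k:k + 12])))
    for name, faces in mesh.face_sets.items():
        nodes = np.unique(faces) + 1
        out.append(f"*NSET, NSET={name}")
        for k in range(0, len(nodes), 12):
            out.append(", ".join(map(str, nodes[k:k + 12])))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def write_msh(path, mesh: LeafletMesh) -> None:
    """Write Gmsh MSH 4.1 ASCII with one volume entity per leaflet."""
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat",
           "$Entities", "0 0 0 3"]
    for li in range(3):
        out.append(f"{li + 1} -50 -50 -50 50 50 50 1 {li + 1} 0")
    out.append("$EndEntities")
    n = mesh.n_nodes
    out += ["$Nodes", f"1 {n} 1 {n}", f"3 1 0 {n}"]
    out += [str(i + 1) for i in range(n)]
    out += [f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in mesh.nodes]
    out.append("$EndNodes")
    blocks = [np.where(mesh.leaflet_id == li)[0] for li in range(3)]
    out += ["$Elements", f"{sum(1 for b in blocks if len(b))} "
            f"{mesh.n_elements} 1 {mesh.n_elements}"]
    for li, sel in enumerate(blocks):
        if not len(sel):
            continue
        out.append(f"3 {li + 1} 11 {len(sel)}")
        for e in sel:
            conn = mesh.elements[e][_GMSH_FROM_ABQ] + 1
            out.append(f"{e + 1} " + " ".join(map(str, conn)))
    out.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_msh(path) -> LeafletMesh:
    """Read back a mesh written by :func:`write_msh` (nodes, tets, labels)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = lines.index("$Nodes")
    ntot = int(lines[i + 1].split()[1])
    i += 2
    nblock = int(lines[i].split()[3])
    i += 1 + nblock  # skip tags
    nodes = np.array([[float(v) for v in lines[i + k].split()]
                      for k in range(nblock)])
    i = lines.index("$Elements")
    header = lines[i + 1].split()
    nblocks, netot = int(header[0]), int(header[1])
    i += 2
    elems, labels, order = [], [], []
    for _ in range(nblocks):
        dim, tag, etype, count = (int(v) for v in lines[i].split())
        i += 1
        for _ in range(count):
            vals = [int(v) for v in lines[i].split()]
            order.append(vals[0])
            conn = np.array(vals[1:]) - 1
            elems.append(conn[_ABQ_FROM_GMSH])
            labels.append(tag - 1)
            i += 1
    idx = np.argsort(order)
    elements = np.asarray(elems)[idx]
    leaflet_id = np.asarray(labels)[idx]
    return LeafletMesh(nodes=nodes, elements=elements, leaflet_id=leaflet_id,
                       thickness=np.nan, fixed_nodes=np.empty(0, np.int64),
                       face_sets={})
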