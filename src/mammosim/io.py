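"""Mesh and surface I/O: Gmsh MSH (v2.2 / v4.1 ASCII), VTU export, PLY/STL/OBJ.

Only the small subset of each format the simulator needs is supported:
tetrahedra and triangles with physical-group tags in MSH, ASCII unstructured
grids with point/cell data in VTU.  Triangulated surfaces go through
:mod:`trimesh`, which handles PLY, STL and OBJ.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import trimesh

from .mesh import (
    LabeledMesh, LabellingError, GeometryError, Patch, Region, boundary_faces,
)

__all__ = [
    "read_mesh", "write_msh", "write_vtu", "export_surface", "load_surface",
    "DEFAULT_REGION_MAP", "DEFAULT_PATCH_MAP",
]

DEFAULT_REGION_MAP = {
    "adipose": Region.ADIPOSE,
    "fibroglandular": Region.FIBROGLANDULAR,
    "wound": Region.WOUND,
}
DEFAULT_PATCH_MAP = {
    "skin": Patch.SKIN,
    "chest": Patch.CHEST,
    "clip_inferior": Patch.CLIP_INFERIOR,
    "clip_superior": Patch.CLIP_SUPERIOR,
    "lateral": Patch.LATERAL,
}

_MSH_TET = 4
_MSH_TRI = 2


def _tokens(text: str):
    for line in text.splitlines():
        line = line.strip()
        if line:
            yield line


def _read_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for line in _tokens(text):
        if line.startswith("$End"):
            current = None
        elif line.startswith("$"):
            current = line[1:]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def _parse_physical_names(lines: list[str]) -> dict[int, str]:
    names = {}
    for line in lines[1:]:
        parts = line.split(maxsplit=2)
        names[int(parts[1])] = parts[2].strip().strip('"')
    return names


def _parse_msh2(sec) -> tuple[np.ndarray, dict[int, list], dict[int, list]]:
    lines = sec["Nodes"]
    n = int(lines[0])
    ids = np.empty(n, dtype=np.int64)
    coords = np.empty((n, 3))
    for i, line in enumerate(lines[1 : n + 1]):
        parts = line.split()
        ids[i] = int(parts[0])
        coords[i] = [float(v) for v in parts[1:4]]
    elines = sec["Elements"]
    tets: dict[int, list] = {}
    tris: dict[int, list] = {}
    for line in elines[1:]:
        parts = [int(v) for v in line.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3] if ntags >= 1 else -1
        conn = parts[3 + ntags:]
        if etype == _MSH_TET:
            tets.setdefault(phys, []).append(conn)
        elif etype == _MSH_TRI:
            tris.setdefault(phys, []).append(conn)
    return ids, coords, tets, tris


def _parse_msh4(sec):
    # entity (dim, tag) -> first physical tag
    ent_phys: dict[tuple[int, int], int] = {}
    if "Entities" in sec:
        lines = sec["Entities"]
        counts = [int(v) for v in lines[0].split()]
        row = 1
        for dim, cnt in enumerate(counts):
            for _ in range(cnt):
                parts = lines[row].split()
                row += 1
                tag = int(parts[0])
                if dim == 0:
                    nphys = int(parts[4])
                    phys = int(parts[5]) if nphys else -1
                else:
                    nphys = int(parts[7])
                    phys = int(parts[8]) if nphys else -1
                ent_phys[(dim, tag)] = phys
    lines = sec["Nodes"]
    nblocks = int(lines[0].split()[0])
    row = 1
    ids_all, coords_all = [], []
    for _ in range(nblocks):
        _, _, _, nb = (int(v) for v in lines[row].split())
        row += 1
        tags = [int(lines[row + i]) for i in range(nb)]
        row += nb
        for i in range(nb):
            coords_all.append([float(v) for v in lines[row + i].split()[:3]])
        row += nb
        ids_all.extend(tags)
    ids = np.array(ids_all, dtype=np.int64)
    coords = np.array(coords_all, dtype=float).reshape(-1, 3)
    lines = sec["Elements"]
    nblocks = int(lines[0].split()[0])
    row = 1
    tets: dict[int, list] = {}
    tris: dict[int, list] = {}
    for _ in range(nblocks):
        dim, etag, etype, nb = (int(v) for v in lines[row].split())
        row += 1
        phys = ent_phys.get((dim, etag), -1)
        for i in range(nb):
            conn = [int(v) for v in lines[row + i].split()][1:]
            if etype == _MSH_TET:
                tets.setdefault(phys, []).append(conn)
            elif etype == _MSH_TRI:
                tris.setdefault(phys, []).append(conn)
        row += nb
    return ids, coords, tets, tris


def read_mesh(
    path,
    region_map: dict | None = None,
    patch_map: dict | None = None,
    physical_names: bool = True,
    scale: float = 1.0,
    skin_thickness: float = 1.5e-3,
) -> LabeledMesh:
    """Read a labelled tet mesh from a Gmsh MSH file (v2.2 or v4.1 ASCII).

    Physical groups are mapped to tissue regions / boundary patches through
    ``region_map`` and ``patch_map`` keyed by physical-group name (or by
    integer tag when the file has no ``$PhysicalNames``).  ``scale`` converts
    the file's length unit to metres (e.g. 1e-3 for millimetre meshes).
    Untagged or unmapped tetrahedra and triangles raise a labelling error.
    """
    region_map = {**DEFAULT_REGION_MAP, **(region_map or {})}
    patch_map = {**DEFAULT_PATCH_MAP, **(patch_map or {})}
    text = Path(path).read_text()
    sec = _read_sections(text)
    if "MeshFormat" not in sec:
        raise LabellingError(f"{path}: not a Gmsh MSH file")
    version = sec["MeshFormat"][0].split()[0]
    names = _parse_physical_names(sec.get("PhysicalNames", ["0"])) \
        if "PhysicalNames" in sec else {}
    if version.startswith("2"):
        ids, coords, tets_by, tris_by = _parse_msh2(sec)
    elif version.startswith("4"):
        ids, coords, tets_by, tris_by = _parse_msh4(sec)
    else:
        raise LabellingError(f"unsupported MSH version {version}")
    if not tets_by:
        raise GeometryError(f"{path}: no tetrahedra found")

    renum = {int(t): i for i, t in enumerate(ids)}

    def _lookup(mapping, phys, what):
        key = names.get(phys, phys)
        if key not in mapping and phys not in mapping:
            raise LabellingError(
                f"{what} physical group {key!r} (tag {phys}) has no label mapping"
            )
        return int(mapping.get(key, mapping.get(phys)))

    tets, regions = [], []
    for phys, conns in sorted(tets_by.items()):
        lab = _lookup(region_map, phys, "volume")
        for conn in conns:
            tets.append([renum[c] for c in conn])
            regions.append(lab)
    tris, patches = [], []
    for phys, conns in sorted(tris_by.items()):
        lab = _lookup(patch_map, phys, "surface")
        for conn in conns:
            tris.append([renum[c] for c in conn])
            patches.append(lab)
    tets = np.array(tets, dtype=np.int64)
    if not tris:
        # derive the boundary and label it skin if the file carries no surfaces
        tris = boundary_faces(tets)
        patches = np.full(tris.shape[0], int(Patch.SKIN), dtype=np.int64)
    else:
        tris = np.array(tris, dtype=np.int64)
        patches = np.array(patches, dtype=np.int64)
    mesh = LabeledMesh(
        coords * scale, tets, np.array(regions, dtype=np.int64),
        tris, patches, skin_thickness=skin_thickness,
    )
    mesh.validate()
    return mesh


_REGION_NAMES = {int(v): k for k, v in DEFAULT_REGION_MAP.items()}
_PATCH_NAMES = {int(v): k for k, v in DEFAULT_PATCH_MAP.items()}


def write_msh(mesh: LabeledMesh, path) -> None:
    """Write the labelled mesh as Gmsh MSH v2.2 ASCII with physical names."""
    buf = _io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    vol_tags = sorted({int(r) for r in mesh.tet_region})
    surf_tags = sorted({int(p) for p in mesh.tri_patch})
    buf.write("$PhysicalNames\n%d\n" % (len(vol_tags) + len(surf_tags)))
    for p in surf_tags:
        buf.write('2 %d "%s"\n' % (100 + p, _PATCH_NAMES[p]))
    for r in vol_tags:
        buf.write('3 %d "%s"\n' % (200 + r, _REGION_NAMES[r]))
    buf.write("$EndPhysicalNames\n$Nodes\n%d\n" % mesh.num_nodes)
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        buf.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    buf.write("$EndNodes\n$Elements\n%d\n" % (mesh.num_tets + len(mesh.boundary_tris)))
    eid = 1
    for tri, p in zip(mesh.boundary_tris + 1, mesh.tri_patch):
        buf.write(f"{eid} 2 2 {100 + p} {100 + p} {tri[0]} {tri[1]} {tri[2]}\n")
        eid += 1
    for tet, r in zip(mesh.tets + 1, mesh.tet_region):
        buf.write(
            f"{eid} 4 2 {200 + r} {200 + r} {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n"
        )
        eid += 1
    buf.write("$EndElements\n")
    Path(path).write_text(buf.getvalue())


def _vtu_array(buf, name, data, n_comp):
    buf.write(
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{n_comp}" format="ascii">\n'
    )
    flat = np.asarray(data, dtype=float).reshape(-1)
    buf.write(" ".join(f"{v:.12g}" for v in flat))
    buf.write("\n</DataArray>\n")


def write_vtu(
    mesh: LabeledMesh, path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    displacement: np.ndarray | None = None,
) -> None:
    """Write the tet mesh (optionally deformed) as an ASCII VTU file."""
    x = mesh.nodes if displacement is None else mesh.nodes + displacement
    point_data = dict(point_data or {})
    cell_data = {"region": mesh.tet_region.astype(float), **(cell_data or {})}
    buf = _io.StringIO()
    buf.write('<?xml version="1.0"?>\n')
    buf.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
    buf.write("<UnstructuredGrid>\n")
    buf.write(f'<Piece NumberOfPoints="{mesh.num_nodes}" NumberOfCells="{mesh.num_tets}">\n')
    buf.write("<Points>\n")
    _vtu_array(buf, "Points", x, 3)
    buf.write("</Points>\n<Cells>\n")
    buf.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
    buf.write(" ".join(str(v) for v in mesh.tets.reshape(-1)))
    buf.write("\n</DataArray>\n")
    buf.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
    buf.write(" ".join(str(4 * (i + 1)) for i in range(mesh.num_tets)))
    buf.write("\n</DataArray>\n")
    buf.write('<DataArray type="UInt8" Name="types" format="ascii">\n')
    buf.write(" ".join("10" for _ in range(mesh.num_tets)))
    buf.write("\n</DataArray>\n</Cells>\n")
    buf.write("<PointData>\n")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        _vtu_array(buf, name, arr, 3 if arr.ndim == 2 else 1)
    buf.write("</PointData>\n<CellData>\n")
    for name, arr in cell_data.items():
        _vtu_array(buf, name, arr, 1)
    buf.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    Path(path).write_text(buf.getvalue())


def export_surface(
    mesh: LabeledMesh, path,
    patches=(Patch.SKIN,),
    displacement: np.ndarray | None = None,
) -> None:
    """Export a boundary-patch surface as PLY/STL/OBJ (by file extension)."""
    from .mesh import extract_patch_surface

    verts, faces = extract_patch_surface(mesh, tuple(patches), displacement)
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    tm.export(str(path))


def load_surface(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a triangulated surface (PLY/STL/OBJ); returns (vertices, faces)."""
    tm = trimesh.load(str(path), force="mesh", process=False)
    return np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64)
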