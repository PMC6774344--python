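"""Mesh exchange in the Gmsh MSH 2.2 ASCII format.

Physical groups carry the region and boundary tags: gel=1 and solution=2 as
cell groups, electrode_left=11, electrode_right=12, insulated=13 as boundary
groups (points in 1D, lines in 2D).  Round-tripping a mesh through
export/import preserves node coordinates to full precision, connectivity and
all tags; importing a mesh that lacks a required tag raises
:class:`~gelpnp.errors.MeshImportError` naming the absent tag.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import MeshImportError
from .geometry import Mesh

__all__ = ["write_msh", "read_msh"]

_REGION_IDS = {"gel": 1, "solution": 2}
_BOUNDARY_IDS = {"electrode_left": 11, "electrode_right": 12, "insulated": 13}
_ID_REGIONS = {v: k for k, v in _REGION_IDS.items()}
_ID_BOUNDARIES = {v: k for k, v in _BOUNDARY_IDS.items()}

# Gmsh element type codes
_PT, _LINE, _TRI = 15, 1, 2


def write_msh(mesh: Mesh, path: str | os.PathLike) -> None:
    """Write the mesh with physical-group tags to an MSH 2.2 ASCII file."""
    lines: list[str] = []
    lines += ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    names = []
    present_regions = sorted(set(mesh.cell_regions.tolist()))
    present_bnd = sorted(set(mesh.boundary_tags.tolist()))
    for tag in present_bnd:
        names.append(f'{mesh.dim - 1} {_BOUNDARY_IDS[tag]} "{tag}"')
    for tag in present_regions:
        names.append(f'{mesh.dim} {_REGION_IDS[tag]} "{tag}"')
    lines += ["$PhysicalNames", str(len(names)), *names, "$EndPhysicalNames"]
    lines += ["$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.nodes, start=1):
        x = float(p[0])
        y = float(p[1]) if mesh.dim == 2 else 0.0
        lines.append(f"{i} {x!r} {y!r} 0.0")
    lines.append("$EndNodes")
    elems = []
    eid = 1
    facet_type = _PT if mesh.dim == 1 else _LINE
    for facet, tag in zip(np.atleast_2d(mesh.boundary_facets), mesh.boundary_tags):
        pid = _BOUNDARY_IDS[tag]
        conn = " ".join(str(int(v) + 1) for v in facet)
        elems.append(f"{eid} {facet_type} 2 {pid} {pid} {conn}")
        eid += 1
    cell_type = _LINE if mesh.dim == 1 else _TRI
    for cell, region in zip(mesh.cells, mesh.cell_regions):
        pid = _REGION_IDS[region]
        conn = " ".join(str(int(v) + 1) for v in cell)
        elems.append(f"{eid} {cell_type} 2 {pid} {pid} {conn}")
        eid += 1
    lines += ["$Elements", str(len(elems)), *elems, "$EndElements"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_section(all_lines: list[str], name: str) -> list[str]:
    try:
        start = all_lines.index(f"${name}")
        end = all_lines.index(f"$End{name}")
    except ValueError:
        raise MeshImportError(f"missing ${name} section") from None
    return all_lines[start + 1:end]


def read_msh(path: str | os.PathLike) -> Mesh:
    """Read an MSH 2.2 ASCII file into a :class:`~gelpnp.geometry.Mesh`.

    Region/boundary tags are recovered from the physical names when present,
    falling back to the package's fixed numeric ids.
    """
    with open(path) as fh:
        all_lines = [ln.strip() for ln in fh if ln.strip()]
    fmt = _read_section(all_lines, "MeshFormat")
    if not fmt or not fmt[0].startswith("2.2"):
        raise MeshImportError("only MSH format 2.2 ASCII is supported")

    id_to_name: dict[int, str] = {}
    if "$PhysicalNames" in all_lines:
        sec = _read_section(all_lines, "PhysicalNames")
        for ln in sec[1:]:
            parts = ln.split(maxsplit=2)
            id_to_name[int(parts[1])] = parts[2].strip('"')
    id_to_name = {**_ID_REGIONS, **_ID_BOUNDARIES, **id_to_name}

    sec = _read_section(all_lines, "Nodes")
    n_nodes = int(sec[0])
    coords = np.empty((n_nodes, 3))
    index_of: dict[int, int] = {}
    for row, ln in enumerate(sec[1:1 + n_nodes]):
        parts = ln.split()
        index_of[int(parts[0])] = row
        coords[row] = [float(v) for v in parts[1:4]]

    sec = _read_section(all_lines, "Elements")
    n_elems = int(sec[0])
    cells, regions, facets, btags = [], [], [], []
    dim = 1
    for ln in sec[1:1 + n_elems]:
        parts = [int(v) for v in ln.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3] if ntags >= 1 else -1
        conn = [index_of[v] for v in parts[3 + ntags:]]
        name = id_to_name.get(phys)
        if etype == _TRI:
            dim = 2
            if name not in _REGION_IDS:
                raise MeshImportError(
                    f"triangle with unknown region tag {phys} ({name!r})"
                )
            cells.append(conn)
            regions.append(name)
        elif etype == _LINE:
            if name in _REGION_IDS:
                dim = 1
                cells.append(sorted(conn))
                regions.append(name)
            elif name in _BOUNDARY_IDS:
                facets.append(conn)
                btags.append(name)
            else:
                raise MeshImportError(
                    f"line element with unknown tag {phys} ({name!r})"
                )
        elif etype == _PT:
            if name not in _BOUNDARY_IDS:
                raise MeshImportError(
                    f"point element with unknown boundary tag {phys} ({name!r})"
                )
            facets.append(conn)
            btags.append(name)
        else:
            raise MeshImportError(f"unsupported element type {etype}")

    if not cells:
        raise MeshImportError("mesh contains no region-tagged cells")
    for required in ("gel", "solution"):
        if required not in regions:
            raise MeshImportError(f"mesh lacks required region tag '{required}'")
    if not facets:
        raise MeshImportError("mesh lacks boundary-tagged facets")

    nodes = coords[:, :dim]
    mesh = Mesh(
        dim=dim,
        nodes=nodes,
        cells=np.array(cells, dtype=np.int64),
        cell_regions=np.array(regions, dtype="<U8"),
        boundary_facets=np.array(facets, dtype=np.int64),
        boundary_tags=np.array(btags, dtype="<U16"),
        geometry=None,
    )
    if dim == 2:
        # enforce CCW orientation on import
        from .geometry import _orient_ccw

        mesh.cells = _orient_ccw(mesh.nodes, mesh.cells)
    return mesh
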