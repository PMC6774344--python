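"""Meshed bath+gel domains with region tags and interface refinement bands.

The computational domain is a rectangular solution bath with an embedded gel
(interval in 1D; square or disc in 2D).  The gel-solution interface always
coincides with mesh facets (conforming mesh), and a band of locally refined
elements of configurable half-width surrounds each interface, where the
electric double (Debye) layers form.

Boundary tags follow the stimulation convention: the left and right exterior
boundaries are the electrodes (``electrode_left``/``electrode_right``); the
top and bottom are ``insulated``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import GeometryError

__all__ = [
    "GeometrySpec",
    "Mesh",
    "REGION_TAGS",
    "BOUNDARY_TAGS",
    "build_interval_mesh",
    "build_square_gel_mesh",
    "build_disc_gel_mesh",
    "build_mesh",
    "check_mesh",
]

REGION_TAGS = ("gel", "solution")
BOUNDARY_TAGS = ("electrode_left", "electrode_right", "insulated")


@dataclass(frozen=True)
class GeometrySpec:
    """Bath/gel geometry and mesh-resolution targets (all lengths in meters).

    ``gel_extent`` is the gel half-width (interval/square) or radius (disc);
    ``refinement_band`` is the half-width of the refined zone around the
    gel-solution interface.
    """

    dimension: int
    bath_extent: tuple[float, ...]
    gel_shape: Literal["interval", "square", "disc"]
    gel_extent: float
    gel_center: tuple[float, ...]
    refinement_band: float
    base_resolution: float
    refined_resolution: float
    symmetric: bool = False

    def __post_init__(self):
        if self.dimension not in (1, 2):
            raise GeometryError("dimension must be 1 or 2")
        if len(self.bath_extent) != self.dimension:
            raise GeometryError("bath_extent must have one entry per axis")
        if len(self.gel_center) != self.dimension:
            raise GeometryError("gel_center must have one entry per axis")
        if self.gel_shape == "interval" and self.dimension != 1:
            raise GeometryError("interval gel requires dimension 1")
        if self.gel_shape in ("square", "disc") and self.dimension != 2:
            raise GeometryError(f"{self.gel_shape} gel requires dimension 2")
        if not self.gel_extent > 0.0:
            raise GeometryError("gel_extent must be positive")
        if not self.refinement_band > 0.0:
            raise GeometryError("refinement_band must be positive")
        if not 0.0 < self.refined_resolution <= self.base_resolution:
            raise GeometryError(
                "need 0 < refined_resolution <= base_resolution"
            )
        # gel strictly inside the bath on every side
        for ax in range(self.dimension):
            lo = self.gel_center[ax] - self.gel_extent
            hi = self.gel_center[ax] + self.gel_extent
            if not (lo > 0.0 and hi < self.bath_extent[ax]):
                raise GeometryError(
                    f"gel must lie strictly inside the bath (axis {ax}: "
                    f"[{lo:g}, {hi:g}] vs [0, {self.bath_extent[ax]:g}])"
                )

    @classmethod
    def interval(cls, bath=1.5e-6, gel_half_width=2.5e-7, center=None,
                 band=2.0e-7, base=3.0e-8, fine=2.0e-9) -> "GeometrySpec":
        center = bath / 2.0 if center is None else center
        return cls(1, (bath,), "interval", gel_half_width, (center,),
                   band, base, fine)


@dataclass
class Mesh:
    """Simplicial mesh with gel/solution region tags and boundary tags.

    ``nodes`` is (n_nodes, dim); ``cells`` is (n_cells, dim+1) vertex
    connectivity (CCW in 2D); ``cell_regions`` holds 'gel'/'solution' per
    cell; ``boundary_facets`` is (n_facets, dim) vertex indices of exterior
    facets (a single vertex in 1D) with ``boundary_tags`` aligned.
    """

    dim: int
    nodes: np.ndarray
    cells: np.ndarray
    cell_regions: np.ndarray
    boundary_facets: np.ndarray
    boundary_tags: np.ndarray
    geometry: GeometrySpec | None = field(default=None, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def cell_measures(self) -> np.ndarray:
        """Length (1D) or area (2D) of every cell."""
        if self.dim == 1:
            x = self.nodes[self.cells, 0]
            return x[:, 1] - x[:, 0]
        p = self.nodes[self.cells]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def region_measure(self, region: str) -> float:
        return float(self.cell_measures()[self.cell_regions == region].sum())

    def interface_nodes(self) -> np.ndarray:
        """Vertices shared by a gel cell and a solution cell."""
        gel = np.unique(self.cells[self.cell_regions == "gel"])
        sol = np.unique(self.cells[self.cell_regions == "solution"])
        return np.intersect1d(gel, sol)


def check_mesh(mesh: Mesh) -> None:
    """Validate the Mesh invariants; raise GeometryError on violation."""
    if set(np.unique(mesh.cell_regions)) - set(REGION_TAGS):
        raise GeometryError("unknown region tag present")
    if mesh.cell_regions.shape[0] != mesh.n_cells:
        raise GeometryError("region tags must partition all cells")
    measures = mesh.cell_measures()
    if not (measures > 0.0).all():
        raise GeometryError("all cell measures must be positive")
    if set(np.unique(mesh.boundary_tags)) - set(BOUNDARY_TAGS):
        raise GeometryError("unknown boundary tag present")
    # every exterior facet carries exactly one tag
    ext = _exterior_facets(mesh)
    tagged = {tuple(sorted(f)) for f in np.atleast_2d(mesh.boundary_facets)}
    if tagged != ext:
        raise GeometryError(
            "boundary facets do not coincide with the exterior facets"
        )
    if len(tagged) != mesh.boundary_facets.shape[0]:
        raise GeometryError("duplicate boundary facet tags")


def _exterior_facets(mesh: Mesh) -> set[tuple[int, ...]]:
    if mesh.dim == 1:
        counts: dict[tuple[int, ...], int] = {}
        for c in mesh.cells:
            for v in c:
                counts[(int(v),)] = counts.get((int(v),), 0) + 1
        return {f for f, n in counts.items() if n == 1}
    counts = {}
    for c in mesh.cells:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            key = tuple(sorted((int(c[i]), int(c[j]))))
            counts[key] = counts.get(key, 0) + 1
    return {f for f, n in counts.items() if n == 1}


def _graded_axis(length: float, must_hit: tuple[float, ...],
                 fine_intervals: list[tuple[float, float]],
                 h_base: float, h_fine: float) -> np.ndarray:
    """1D node positions on [0, length]: uniform-per-segment grading.

    Every value in ``must_hit`` and every fine-interval edge becomes an exact
    node; element size is <= h_fine inside the fine intervals and <= h_base
    outside.
    """
    pts = {0.0, length, *must_hit}
    for lo, hi in fine_intervals:
        for edge in (lo, hi):
            if 0.0 < edge < length:
                pts.add(edge)
    breaks = np.array(sorted(pts))
    # drop breakpoints that coincide to floating tolerance
    keep = [0]
    for i in range(1, len(breaks)):
        if breaks[i] - breaks[keep[-1]] > 1e-14 * length:
            keep.append(i)
    breaks = breaks[keep]
    nodes = [0.0]
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        fine = any(lo - 1e-12 * length <= mid <= hi + 1e-12 * length
                   for lo, hi in fine_intervals)
        h = h_fine if fine else h_base
        n = max(1, int(math.ceil((b - a) / h - 1e-12)))
        seg = np.linspace(a, b, n + 1)[1:]
        nodes.extend(seg.tolist())
    return np.array(nodes)


def _interface_band_axis(length: float, interfaces: tuple[float, float],
                         band: float, h_base: float, h_fine: float) -> np.ndarray:
    fine = [(x - band, x + band) for x in interfaces]
    return _graded_axis(length, interfaces, fine, h_base, h_fine)


def build_interval_mesh(spec: GeometrySpec) -> Mesh:
    """Graded 1D mesh of [0, bath_extent] with gel cells spanning exactly
    [center - half_width, center + half_width]."""
    if spec.dimension != 1:
        raise GeometryError("build_interval_mesh requires dimension 1")
    L = spec.bath_extent[0]
    x0 = spec.gel_center[0] - spec.gel_extent
    x1 = spec.gel_center[0] + spec.gel_extent
    x = _interface_band_axis(L, (x0, x1), spec.refinement_band,
                             spec.base_resolution, spec.refined_resolution)
    nodes = x[:, None]
    cells = np.column_stack([np.arange(len(x) - 1), np.arange(1, len(x))])
    mids = 0.5 * (x[:-1] + x[1:])
    regions = np.where((mids > x0) & (mids < x1), "gel", "solution")
    facets = np.array([[0], [len(x) - 1]])
    tags = np.array(["electrode_left", "electrode_right"])
    return Mesh(1, nodes, cells, regions.astype("<U8"), facets, tags,
                geometry=spec)


def _tensor_triangulation(x: np.ndarray, y: np.ndarray,
                          symmetric: bool) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the tensor grid x (X) y.

    Default: split each quad along the same diagonal.  ``symmetric``: split
    each quad into four triangles through its centroid, which makes the node
    set and connectivity mirror-symmetric whenever the axis spacings are.
    """
    nx, ny = len(x), len(y)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    def vid(i, j):
        return i * ny + j

    tris = []
    if not symmetric:
        for i in range(nx - 1):
            for j in range(ny - 1):
                a, b = vid(i, j), vid(i + 1, j)
                c, d = vid(i + 1, j + 1), vid(i, j + 1)
                tris.append((a, b, c))
                tris.append((a, c, d))
        return nodes, np.array(tris, dtype=np.int64)

    centers = []
    base = nodes.shape[0]
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            cid = base + len(centers)
            centers.append([0.5 * (x[i] + x[i + 1]), 0.5 * (y[j] + y[j + 1])])
            tris += [(a, b, cid), (b, c, cid), (c, d, cid), (d, a, cid)]
    nodes = np.vstack([nodes, np.array(centers)])
    return nodes, np.array(tris, dtype=np.int64)


def _tag_2d_boundary(nodes: np.ndarray, cells: np.ndarray,
                     Lx: float, Ly: float) -> tuple[np.ndarray, np.ndarray]:
    counts: dict[tuple[int, int], int] = {}
    for c in cells:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            key = (int(min(c[i], c[j])), int(max(c[i], c[j])))
            counts[key] = counts.get(key, 0) + 1
    facets, tags = [], []
    tol = 1e-12 * max(Lx, Ly)
    for (a, b), n in counts.items():
        if n != 1:
            continue
        pa, pb = nodes[a], nodes[b]
        if abs(pa[0]) < tol and abs(pb[0]) < tol:
            tag = "electrode_left"
        elif abs(pa[0] - Lx) < tol and abs(pb[0] - Lx) < tol:
            tag = "electrode_right"
        else:
            tag = "insulated"
        facets.append((a, b))
        tags.append(tag)
    order = np.lexsort((np.array(facets)[:, 1], np.array(facets)[:, 0]))
    return np.array(facets)[order], np.array(tags, dtype="<U16")[order]


def _orient_ccw(nodes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    p = nodes[cells]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    neg = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) < 0
    cells = cells.copy()
    cells[neg] = cells[neg][:, [0, 2, 1]]
    return cells


def build_square_gel_mesh(spec: GeometrySpec) -> Mesh:
    """2D bath with an embedded square gel; graded tensor-grid triangulation."""
    if spec.dimension != 2 or spec.gel_shape != "square":
        raise GeometryError("build_square_gel_mesh requires a 2D square gel")
    Lx, Ly = spec.bath_extent
    cx, cy = spec.gel_center
    a = spec.gel_extent
    x = _interface_band_axis(Lx, (cx - a, cx + a), spec.refinement_band,
                             spec.base_resolution, spec.refined_resolution)
    y = _interface_band_axis(Ly, (cy - a, cy + a), spec.refinement_band,
                             spec.base_resolution, spec.refined_resolution)
    nodes, cells = _tensor_triangulation(x, y, spec.symmetric)
    cells = _orient_ccw(nodes, cells)
    cent = nodes[cells].mean(axis=1)
    inside = (np.abs(cent[:, 0] - cx) < a) & (np.abs(cent[:, 1] - cy) < a)
    regions = np.where(inside, "gel", "solution").astype("<U8")
    facets, tags = _tag_2d_boundary(nodes, cells, Lx, Ly)
    return Mesh(2, nodes, cells, regions, facets, tags, geometry=spec)


# Safety factor applied to the requested element sizes before the square-to-disc
# blend map: the map stretches edges by at most ~1.6x in the blend zone.
_DISC_MAP_STRETCH = 1.8


def _frame_refined_square(Lx, Ly, cx, cy, a, frame, h_base, h_fine,
                          symmetric) -> Mesh:
    """Square-gel mesh whose fine zone is the full frame [c-frame, c+frame]
    in both axes (pre-image of a wide disc refinement annulus)."""
    x = _graded_axis(Lx, (cx - a, cx + a),
                     [(cx - frame, cx + frame)], h_base, h_fine)
    y = _graded_axis(Ly, (cy - a, cy + a),
                     [(cy - frame, cy + frame)], h_base, h_fine)
    nodes, cells = _tensor_triangulation(x, y, symmetric)
    cells = _orient_ccw(nodes, cells)
    cent = nodes[cells].mean(axis=1)
    inside = (np.abs(cent[:, 0] - cx) < a) & (np.abs(cent[:, 1] - cy) < a)
    regions = np.where(inside, "gel", "solution").astype("<U8")
    facets, tags = _tag_2d_boundary(nodes, cells, Lx, Ly)
    return Mesh(2, nodes, cells, regions, facets, tags, geometry=None)


def build_disc_gel_mesh(spec: GeometrySpec) -> Mesh:
    """2D bath with an embedded circular gel.

    Built by meshing a square gel of half-width equal to the radius, then
    morphing the interior with a square-to-disc blend map: the square contour
    of inf-norm level m maps to the circle of radius m for m <= r, blending
    back to the identity at twice the radius.  The interface is therefore a
    polygon whose vertices lie exactly on the circle, with vertex count set by
    the refined resolution.
    """
    if spec.dimension != 2 or spec.gel_shape != "disc":
        raise GeometryError("build_disc_gel_mesh requires a 2D disc gel")
    Lx, Ly = spec.bath_extent
    cx, cy = spec.gel_center
    r = spec.gel_extent
    clearance = min(cx, Lx - cx, cy, Ly - cy)
    if r >= clearance:
        raise GeometryError("disc radius exceeds the bath clearance")
    blend_outer = min(2.0 * r, 0.98 * clearance)
    # The annulus |rho - r| <= band pulls back to the inf-norm band
    # [r - band, r + band] of the pre-map square, which a tensor grid can
    # only refine by keeping both axes fine across the whole outer frame.
    frame = r + spec.refinement_band
    mesh = _frame_refined_square(
        Lx, Ly, cx, cy, r, frame,
        spec.base_resolution / _DISC_MAP_STRETCH,
        spec.refined_resolution / _DISC_MAP_STRETCH,
        spec.symmetric,
    )
    p = mesh.nodes - np.array([cx, cy])
    m = np.abs(p).max(axis=1)
    rad = np.hypot(p[:, 0], p[:, 1])
    safe = np.where(rad > 0, rad, 1.0)
    mapped = mesh.nodes.copy()
    gel_zone = (m > 0) & (m <= r)
    mapped[gel_zone] = (
        np.array([cx, cy]) + p[gel_zone] * (m[gel_zone] / safe[gel_zone])[:, None]
    )
    zone = (m > r) & (m < blend_outer)
    w = (blend_outer - m[zone]) / (blend_outer - r)
    target = p[zone] * (m[zone] / safe[zone])[:, None]
    mapped[zone] = np.array([cx, cy]) + (1 - w[:, None]) * p[zone] + w[:, None] * target
    out = Mesh(2, mapped, mesh.cells, mesh.cell_regions,
               mesh.boundary_facets, mesh.boundary_tags, geometry=spec)
    if not (out.cell_measures() > 0).all():
        raise GeometryError("disc blend map produced an inverted cell; "
                            "reduce refinement contrast or band width")
    return out


def build_mesh(spec: GeometrySpec) -> Mesh:
    """Dispatch on gel shape."""
    if spec.gel_shape == "interval":
        return build_interval_mesh(spec)
    if spec.gel_shape == "square":
        return build_square_gel_mesh(spec)
    return build_disc_gel_mesh(spec)
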