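"""Triangulated lumen-surface geometry.

The lumen wall is represented as a triangle mesh with per-node outward unit
normals, parameterized by an axial arc-length coordinate ``s`` (mm) and a
circumferential angle ``theta`` (rad) about a straight vessel axis.  The
module also provides the four-region segmentation of a cuffed vessel
(upstream outside the plaque, upstream plaque, cuff, downstream) and the
areal-stenosis arithmetic for the tapered cuff.

Coordinates are millimetres throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import trimesh as _trimesh

logger = logging.getLogger(__name__)

#: STL stores a triangle soup; vertices closer than this (mm) are merged.
MERGE_TOL_MM = 1e-6

#: Triangles with area below this (mm^2) are dropped as degenerate.
DEGENERATE_AREA_MM2 = 1e-12

#: The four vessel regions, ordered from inlet to outlet.
REGIONS = ("upstream_outside", "upstream_plaque", "cuff", "downstream")


class MeshError(ValueError):
    """Raised for malformed meshes, files or geometric preconditions."""


def _triangle_normals_areas(nodes: np.ndarray, triangles: np.ndarray):
    v0 = nodes[triangles[:, 0]]
    v1 = nodes[triangles[:, 1]]
    v2 = nodes[triangles[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    area2 = np.linalg.norm(cross, axis=1)  # twice the triangle area
    return cross, area2 / 2.0


def _vertex_normals(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted per-node normals from triangle geometry."""
    cross, _ = _triangle_normals_areas(nodes, triangles)
    vn = np.zeros_like(nodes)
    for k in range(3):
        np.add.at(vn, triangles[:, k], cross)
    norms = np.linalg.norm(vn, axis=1)
    if np.any(norms == 0):
        raise MeshError("degenerate vertex normal (zero area-weighted sum)")
    return vn / norms[:, None]


@dataclass
class TriSurfaceMesh:
    """Triangulated lumen wall with outward per-node unit normals."""

    nodes: np.ndarray      # (n_nodes, 3) mm
    triangles: np.ndarray  # (n_triangles, 3) int node indices
    normals: np.ndarray    # (n_nodes, 3) outward unit vectors

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if len(self.normals) != len(self.nodes):
            raise MeshError("normal count does not match node count")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.nodes)
        ):
            raise MeshError("triangle references an invalid node index")
        lens = np.linalg.norm(self.normals, axis=1)
        if len(lens) and np.max(np.abs(lens - 1.0)) > 1e-8:
            raise MeshError("node normals are not unit length")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


@dataclass
class CenterlineFrame:
    """Cylindrical parameterization of a tube-like mesh about a straight axis.

    ``axial`` is the arc-length coordinate s (mm) of each node along the axis,
    ``angular`` the circumferential angle theta in [0, 2*pi), and ``length``
    the total axial extent L.
    """

    axial: np.ndarray    # (n_nodes,) s in mm
    angular: np.ndarray  # (n_nodes,) theta in rad
    length: float        # L in mm
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.axial = np.asarray(self.axial, dtype=float)
        self.angular = np.asarray(self.angular, dtype=float)
        if np.any(self.axial < -1e-9) or np.any(self.axial > self.length + 1e-9):
            raise MeshError("axial coordinates fall outside [0, L]")
        if np.any(self.angular < 0) or np.any(self.angular >= 2 * np.pi):
            raise MeshError("angular coordinates fall outside [0, 2*pi)")


@dataclass
class RegionLabels:
    """Per-node region assignment of a (cuffed or control) vessel.

    Boundary ties go to the more distal region, so the cuff interval is
    closed: s == plaque_start is upstream_plaque, s == cuff_start and
    s == cuff_end are cuff.
    """

    labels: np.ndarray        # (n_nodes,) strings from REGIONS
    plaque_start_mm: float    # cuff entrance minus the plaque extent
    cuff_start_mm: float
    cuff_end_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(REGIONS)
        if bad:
            raise MeshError(f"unknown region labels: {sorted(bad)}")

    def counts(self) -> dict:
        return {r: int(np.sum(self.labels == r)) for r in REGIONS}


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def read_stl(path) -> TriSurfaceMesh:
    """Read an ASCII or binary STL file into a :class:`TriSurfaceMesh`.

    STL stores an unindexed triangle soup, so vertices are merged within
    ``MERGE_TOL_MM`` and per-node normals are recomputed (area-weighted)
    from the geometry rather than trusted from the file.  Zero-area
    triangles are dropped with a logged count.
    """
    try:
        raw = _trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise MeshError(f"malformed STL file {path!s}: {exc}") from exc
    verts = np.asarray(raw.vertices, dtype=float)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if verts.size == 0 or faces.size == 0:
        raise MeshError(f"STL file {path!s} contains no triangles")

    keys = np.round(verts / MERGE_TOL_MM).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    nodes = verts[first]
    triangles = inverse[faces]

    # drop triangles that became degenerate after merging
    distinct = (
        (triangles[:, 0] != triangles[:, 1])
        & (triangles[:, 1] != triangles[:, 2])
        & (triangles[:, 0] != triangles[:, 2])
    )
    _, areas = _triangle_normals_areas(nodes, triangles)
    keep = distinct & (areas > DEGENERATE_AREA_MM2)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("read_stl: dropped %d degenerate triangle(s)", n_dropped)
    triangles = triangles[keep]
    if len(triangles) == 0:
        raise MeshError(f"STL file {path!s}: all triangles degenerate")
    return TriSurfaceMesh(nodes, triangles, _vertex_normals(nodes, triangles))


def write_stl(mesh: TriSurfaceMesh, path) -> None:
    """Write a binary STL with facet normals derived from the geometry."""
    if mesh.n_triangles == 0:
        raise MeshError("refusing to write an empty mesh")
    tm = _trimesh.Trimesh(
        vertices=mesh.nodes, faces=mesh.triangles, process=False
    )
    try:
        tm.export(str(path), file_type="stl")
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write STL to {path!s}: {exc}") from exc


# ---------------------------------------------------------------------------
# Structured tube construction
# ---------------------------------------------------------------------------

def build_tube_mesh(
    radius_profile: Callable[[np.ndarray], np.ndarray],
    length: float,
    n_axial: int,
    n_circ: int,
) -> TriSurfaceMesh:
    """Structured open tube of ``n_axial`` rings x ``n_circ`` nodes.

    The tube is aligned with +z, spans s in [0, length], and has outward
    normals.  ``radius_profile`` maps axial position s (mm) to radius R(s)
    (mm) and must be positive on [0, length].
    """
    if n_axial < 2 or n_circ < 3:
        raise MeshError("need n_axial >= 2 and n_circ >= 3")
    s = np.linspace(0.0, float(length), n_axial)
    radii = np.broadcast_to(np.asarray(radius_profile(s), dtype=float), s.shape)
    if np.any(radii <= 0):
        raise MeshError("radius profile must be positive over the tube")
    theta = np.arange(n_circ) * (2 * np.pi / n_circ)

    ss, tt = np.meshgrid(s, theta, indexing="ij")
    rr = np.repeat(radii[:, None], n_circ, axis=1)
    nodes = np.column_stack(
        [(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel(), ss.ravel()]
    )

    i = np.repeat(np.arange(n_axial - 1), n_circ)
    j = np.tile(np.arange(n_circ), n_axial - 1)
    a = i * n_circ + j
    b = i * n_circ + (j + 1) % n_circ
    c = (i + 1) * n_circ + j
    d = (i + 1) * n_circ + (j + 1) % n_circ
    # consistent diagonal a-d: outward winding for CCW theta about +z
    triangles = np.concatenate(
        [np.column_stack([a, b, d]), np.column_stack([a, d, c])]
    )
    return TriSurfaceMesh(nodes, triangles, _vertex_normals(nodes, triangles))


# ---------------------------------------------------------------------------
# Parameterization and adjacency
# ---------------------------------------------------------------------------

def parameterize(
    mesh: TriSurfaceMesh,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> CenterlineFrame:
    """Cylindrical (s, theta) coordinates about a straight axis.

    s is the projection of each node onto ``axis`` relative to ``origin``;
    theta is measured in the cross-plane with a deterministic in-plane basis
    (the coordinate axis least aligned with ``axis``), shifted to [0, 2*pi).
    """
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    origin = np.asarray(origin, dtype=float)
    rel = mesh.nodes - origin
    s = rel @ a
    if s.min() < -1e-6:
        raise MeshError("nodes project before the origin; check axis/origin")
    s = np.clip(s, 0.0, None)

    e = np.zeros(3)
    e[int(np.argmin(np.abs(a)))] = 1.0
    e1 = e - (e @ a) * a
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)

    v = rel - s[:, None] * a
    x, y = v @ e1, v @ e2
    r = np.hypot(x, y)
    if np.any(r < 1e-9):
        raise MeshError("node lies on the vessel axis; theta undefined")
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    return CenterlineFrame(axial=s, angular=theta, length=float(s.max()),
                           axis=a, origin=origin)


def node_neighbors(mesh: TriSurfaceMesh) -> list:
    """Edge adjacency: node k is a neighbour of j iff edge (j, k) belongs
    to at least one triangle.  Returns a list of sorted index arrays."""
    t = mesh.triangles
    src = np.concatenate([t[:, 0], t[:, 1], t[:, 2], t[:, 1], t[:, 2], t[:, 0]])
    dst = np.concatenate([t[:, 1], t[:, 2], t[:, 0], t[:, 0], t[:, 1], t[:, 2]])
    pairs = np.unique(np.column_stack([src, dst]), axis=0)
    out = [np.empty(0, dtype=np.int64)] * mesh.n_nodes
    bounds = np.searchsorted(pairs[:, 0], np.arange(mesh.n_nodes + 1))
    for j in range(mesh.n_nodes):
        out[j] = pairs[bounds[j]:bounds[j + 1], 1]
    return out


# ---------------------------------------------------------------------------
# Region segmentation
# ---------------------------------------------------------------------------

def _assign_labels(s: np.ndarray, plaque_start: float, cuff_start: float,
                   cuff_end: float) -> np.ndarray:
    labels = np.empty(len(s), dtype=object)
    labels[s < plaque_start] = "upstream_outside"
    labels[(s >= plaque_start) & (s < cuff_start)] = "upstream_plaque"
    labels[(s >= cuff_start) & (s <= cuff_end)] = "cuff"
    labels[s > cuff_end] = "downstream"
    return labels


def segment_regions(
    frame: CenterlineFrame,
    cuff_start: float,
    cuff_end: float,
    plaque_extent: float = 1.6,
) -> RegionLabels:
    """Four-region segmentation of the instrumented vessel.

    The upstream plaque region extends ``plaque_extent`` mm (default 1.6,
    from histological plaque-length measurements) proximal to the cuff
    entrance.  Boundary nodes go to the more distal region.
    """
    if plaque_extent <= 0:
        raise MeshError("plaque_extent must be positive")
    if not (0 < cuff_start < cuff_end < frame.length):
        raise MeshError("cuff interval must lie strictly inside the vessel")
    plaque_start = cuff_start - plaque_extent
    if plaque_start < 0:
        raise MeshError("plaque region extends beyond the proximal vessel end")
    return RegionLabels(
        labels=_assign_labels(frame.axial, plaque_start, cuff_start, cuff_end),
        plaque_start_mm=plaque_start,
        cuff_start_mm=cuff_start,
        cuff_end_mm=cuff_end,
    )


def control_regions(
    frame_control: CenterlineFrame,
    labels_instrumented: RegionLabels,
    frame_instrumented: CenterlineFrame,
) -> RegionLabels:
    """Mirror the instrumented-vessel regions onto the control vessel.

    Boundaries are anchored to the distal (outlet) end: each region boundary
    sits at the same distance from the end of the control vessel as from the
    end of the instrumented vessel.
    """
    shift = frame_control.length - frame_instrumented.length
    plaque_start = labels_instrumented.plaque_start_mm + shift
    cuff_start = labels_instrumented.cuff_start_mm + shift
    cuff_end = labels_instrumented.cuff_end_mm + shift
    if plaque_start < 0:
        raise MeshError(
            "control vessel is shorter than the region span it must carry"
        )
    return RegionLabels(
        labels=_assign_labels(frame_control.axial, plaque_start, cuff_start,
                              cuff_end),
        plaque_start_mm=plaque_start,
        cuff_start_mm=cuff_start,
        cuff_end_mm=cuff_end,
    )


def areal_stenosis(d_inlet: float, d_outlet: float) -> float:
    """Percent areal stenosis of a circular taper, 100*(1 - (d_out/d_in)^2).

    For the cuff's 500 -> 250 um taper this is 75%.
    """
    if d_inlet <= 0 or d_outlet <= 0:
        raise ValueError("diameters must be positive")
    return 100.0 * (1.0 - (d_outlet / d_inlet) ** 2)
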