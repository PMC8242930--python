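"""Convex hulls of skeletal segments and planar subdivision of elongate
segments (tails) into equal-extent pieces.

The hull is computed with the Quickhull algorithm (scipy.spatial.ConvexHull,
backed by Qhull). Hull facets are re-emitted as an outward-oriented
watertight triangle mesh so the result feeds directly into mass_properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .mass_properties import BSPVector, mass_properties
from .mesh_io import TriangleMesh, require_valid

__all__ = [
    "HullResult",
    "DegenerateInputError",
    "convex_hull",
    "hull_bsp",
    "split_along_axis",
]


class DegenerateInputError(ValueError):
    """Raised for point sets with no 3D extent (coplanar/collinear/too few)."""


@dataclass(frozen=True)
class HullResult:
    hull: TriangleMesh
    input_vertex_count: int
    hull_vertex_count: int


def _as_points(points_or_mesh) -> np.ndarray:
    if isinstance(points_or_mesh, TriangleMesh):
        return points_or_mesh.vertices
    pts = np.asarray(points_or_mesh, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) point array, got shape {pts.shape}")
    return pts


def convex_hull(points_or_mesh) -> HullResult:
    """Convex hull of a 3D point set (or of a mesh's vertices).

    Degenerate input (fewer than 4 points, or all points coplanar) raises
    DegenerateInputError rather than returning a zero-volume pseudo-hull.
    The result is independent of input point order up to vertex relabeling.
    """
    points = _as_points(points_or_mesh)
    if len(points) < 4:
        raise DegenerateInputError(
            f"convex hull needs >= 4 points, got {len(points)}"
        )
    try:
        qh = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateInputError(f"degenerate point set: {exc}") from exc

    used = np.unique(qh.simplices)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    vertices = points[used]
    faces = remap[qh.simplices]

    # Qhull does not guarantee CCW simplices; orient each by its own
    # outward plane equation.
    normals = qh.equations[:, :3]
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    tri_normals = np.cross(b - a, c - a)
    flip = np.einsum("ij,ij->i", tri_normals, normals) < 0
    faces[flip] = faces[flip][:, ::-1]

    mesh = TriangleMesh(vertices, faces)
    return HullResult(
        hull=mesh,
        input_vertex_count=len(points),
        hull_vertex_count=len(vertices),
    )


def hull_bsp(skeleton_mesh: TriangleMesh, density: float = 1000.0) -> BSPVector:
    """Naive convex-hull BSPs of a skeletal segment: mass properties of the
    hull of the segment's vertices at the given uniform density."""
    result = convex_hull(skeleton_mesh)
    return mass_properties(result.hull, density)


# ---------------------------------------------------------------------------
# Planar splitting
# ---------------------------------------------------------------------------


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Largest-variance eigenvector of the vertex cloud, sign-disambiguated
    to point toward the vertex with the largest coordinate along it."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]
    proj = centered @ axis
    if abs(proj.min()) > abs(proj.max()):
        axis = -axis
    return axis


def _edge_plane_point(pi, pj, di, dj) -> np.ndarray:
    """Intersection of segment (pi, pj) with the plane where the signed
    distances di, dj vanish, computed from a canonical endpoint ordering so
    the result is bitwise identical no matter which triangle asks."""
    if tuple(pj) < tuple(pi):
        pi, pj = pj, pi
        di, dj = dj, di
    t = di / (di - dj)
    return pi + t * (pj - pi)


def _clip_mesh_halfspace(
    mesh: TriangleMesh, axis: np.ndarray, lo: float, hi: float
) -> TriangleMesh:
    """Intersect a watertight mesh with the slab lo <= axis.p <= hi and
    close the cut cross-sections with centroid-fan caps.

    Cut planes are assumed nudged off every vertex (no zero signed
    distances), so each straddling triangle crosses each plane exactly
    twice and the cut boundary is a set of clean directed edges.
    """

    def clip_tris(tris: list[np.ndarray], offset: float, keep_above: bool):
        """Clip triangles against one plane; returns kept triangles and the
        cut-boundary edges directed as the kept surface traverses them."""
        kept: list[np.ndarray] = []
        boundary: list[tuple[np.ndarray, np.ndarray]] = []
        sign = 1.0 if keep_above else -1.0
        for tri in tris:
            d = sign * (tri @ axis - offset)
            if np.all(d > 0):
                kept.append(tri)
                continue
            if np.all(d < 0):
                continue
            poly: list[np.ndarray] = []
            q_out = q_in = None
            for i in range(3):
                j = (i + 1) % 3
                di, dj = d[i], d[j]
                if di > 0:
                    poly.append(tri[i])
                if di > 0 and dj < 0:
                    q_out = _edge_plane_point(tri[i], tri[j], di, dj)
                    poly.append(q_out)
                elif di < 0 and dj > 0:
                    q_in = _edge_plane_point(tri[i], tri[j], di, dj)
                    poly.append(q_in)
            if q_out is not None and q_in is not None:
                # The kept polygon traverses the plane edge q_out -> q_in.
                boundary.append((q_out, q_in))
            if len(poly) >= 3:
                for k in range(1, len(poly) - 1):
                    kept.append(np.array([poly[0], poly[k], poly[k + 1]]))
        return kept, boundary

    tris = [mesh.vertices[f] for f in mesh.faces]
    tris, lo_edges = clip_tris(tris, lo, keep_above=True)
    tris, hi_edges = clip_tris(tris, hi, keep_above=False)
    out_tris: list[np.ndarray] = list(tris)

    # Cap each cut with a signed centroid fan traversing the boundary loop
    # opposite to the wall surface; this is exact (Green's theorem) even for
    # non-convex loops and pairs every fan edge within each loop.
    for edges in (lo_edges, hi_edges):
        if not edges:
            continue
        pts = np.array([p for e in edges for p in e])
        centroid = pts.mean(axis=0)
        for q_out, q_in in edges:
            out_tris.append(np.array([q_in, q_out, centroid]))

    if not out_tris:
        raise ValueError("slab does not intersect the mesh (empty piece)")
    flat = np.concatenate(out_tris).reshape(-1, 3)
    # Weld exactly: clip intersections of the same edge produce bitwise
    # identical points because they are computed once per input edge per
    # plane in a fixed order.
    seen: dict[tuple[float, float, float], int] = {}
    idx = np.empty(len(flat), dtype=np.int64)
    verts: list[tuple[float, float, float]] = []
    for i, p in enumerate(map(tuple, flat)):
        j = seen.get(p)
        if j is None:
            j = len(verts)
            seen[p] = j
            verts.append(p)
        idx[i] = j
    faces = idx.reshape(-1, 3)
    good = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return _collapse_slivers(TriangleMesh(np.array(verts), faces[good]))


def _collapse_slivers(mesh: TriangleMesh) -> TriangleMesh:
    """Remove near-zero-area faces produced by clipping edges that graze a
    cut plane, by collapsing their shortest edge (union-find vertex merge).
    Volume changes by O(sliver size), far below the conservation tolerance."""
    v = mesh.vertices
    scale = max(float(np.abs(v).max(initial=0.0)), 1.0)
    area_tol = 1e-13 * scale * scale  # on 2*area; validate_mesh flags at 1e-14

    parent = np.arange(len(v))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    areas2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    for fi in np.nonzero(areas2 <= area_tol)[0]:
        tri = mesh.faces[fi]
        lengths = [float(np.linalg.norm(v[tri[(k + 1) % 3]] - v[tri[k]])) for k in range(3)]
        k = int(np.argmin(lengths))
        i, j = find(int(tri[k])), find(int(tri[(k + 1) % 3]))
        if i != j:
            parent[max(i, j)] = min(i, j)

    if np.all(parent == np.arange(len(v))):
        return mesh
    roots = np.array([find(i) for i in range(len(v))])
    faces = roots[mesh.faces]
    good = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[good]
    used = np.unique(faces)
    remap = np.full(len(v), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(v[used], remap[faces])


def split_along_axis(
    mesh: TriangleMesh, n_segments: int, axis="auto"
) -> list[TriangleMesh]:
    """Cut a watertight mesh into `n_segments` pieces of equal extent along
    an axis with n-1 parallel planes, capping each cross-section.

    `axis="auto"` uses the principal axis of the vertex cloud; pieces are
    returned proximal-to-distal (decreasing coordinate along the axis).
    Volume is conserved: the piece volumes sum to the input volume.
    """
    if n_segments < 1:
        raise ValueError(f"n_segments must be >= 1, got {n_segments}")
    require_valid(mesh, "split input")
    if n_segments == 1:
        return [mesh.copy()]

    if isinstance(axis, str):
        if axis != "auto":
            raise ValueError(f"axis must be a 3-vector or 'auto', got {axis!r}")
        axis_vec = _principal_axis(mesh.vertices)
    else:
        axis_vec = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis_vec)
        if norm == 0:
            raise ValueError("axis vector must be nonzero")
        axis_vec = axis_vec / norm

    proj = mesh.vertices @ axis_vec
    lo, hi = float(proj.min()), float(proj.max())
    if hi - lo <= 0:
        raise ValueError("mesh has zero extent along the requested axis")
    cuts = np.linspace(lo, hi, n_segments + 1)
    # Widen the terminal slabs so boundary vertices are never clipped away,
    # and nudge interior planes off any vertex they graze: the clipper
    # assumes strictly nonzero signed distances.
    eps = (hi - lo) * 1e-9
    cuts[0] -= eps
    cuts[-1] += eps
    tol = (hi - lo) * 1e-12
    for k in range(1, n_segments):
        while np.any(np.abs(proj - cuts[k]) <= tol):
            cuts[k] += eps

    pieces = []
    for k in range(n_segments):
        piece = _clip_mesh_halfspace(mesh, axis_vec, cuts[k], cuts[k + 1])
        report_volume = piece.signed_volume()
        if report_volume <= 0:
            raise ValueError(f"degenerate split: piece {k} has volume {report_volume}")
        pieces.append(piece)
    # proximal -> distal: decreasing coordinate along the axis
    return pieces[::-1]
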