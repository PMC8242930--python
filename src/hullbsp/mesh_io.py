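"""Triangle-mesh container, file I/O (OBJ / STL / PLY), validation, and
primitive generators.

Coordinate convention: x = craniocaudal, y = mediolateral, z = vertical.
All lengths are meters; no unit inference is performed on file input.
Faces are 0-based vertex-index triples, counter-clockwise when viewed
from outside (outward normals).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriangleMesh",
    "ValidationReport",
    "MeshFormatError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "make_box",
    "make_icosphere",
    "make_prism",
]


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed under its named format."""


class MeshValidationError(ValueError):
    """Raised when an operation requires a valid (watertight, oriented) mesh."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, meters.
    faces : (m, 3) int array, 0-based indices, CCW from outside.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def signed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (positive for
        outward-oriented closed surfaces)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=float), self.faces.copy())

    def transformed(self, rotation) -> "TriangleMesh":
        """Apply a 3x3 linear map to the vertices (faces unchanged)."""
        rotation = np.asarray(rotation, dtype=float)
        return TriangleMesh(self.vertices @ rotation.T, self.faces.copy())

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class ValidationReport:
    watertight: bool
    consistently_oriented: bool
    positive_volume: bool
    degenerate_face_indices: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.watertight
            and self.consistently_oriented
            and self.positive_volume
            and not self.degenerate_face_indices
        )


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Check watertightness, orientation consistency, signed volume and
    face degeneracy. Report-only; the mesh is not modified."""
    edges: dict[tuple[int, int], list[int]] = {}
    for f in mesh.faces:
        for i in range(3):
            a, b = int(f[i]), int(f[(i + 1) % 3])
            key = (a, b) if a < b else (b, a)
            edges.setdefault(key, []).append(1 if a < b else -1)
    watertight = all(len(v) == 2 for v in edges.values())
    # Consistent orientation: each shared edge traversed once in each direction.
    consistently_oriented = watertight and all(sum(v) == 0 for v in edges.values())

    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    areas2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    scale = max(float(np.abs(v).max(initial=0.0)), 1.0)
    degenerate = np.nonzero(areas2 <= 1e-14 * scale * scale)[0].tolist()

    positive_volume = mesh.signed_volume() > 0.0
    return ValidationReport(
        watertight=watertight,
        consistently_oriented=consistently_oriented,
        positive_volume=positive_volume,
        degenerate_face_indices=degenerate,
    )


def require_valid(mesh: TriangleMesh, what: str = "mesh") -> None:
    """Raise MeshValidationError unless the mesh passes all validation flags.

    A consistently oriented mesh with negative signed volume is repaired by
    a global face flip; mixed orientation is an error.
    """
    report = validate_mesh(mesh)
    if not report.watertight:
        raise MeshValidationError(f"{what} is not watertight")
    if not report.consistently_oriented:
        raise MeshValidationError(f"{what} has inconsistent face orientation")
    if report.degenerate_face_indices:
        raise MeshValidationError(
            f"{what} has degenerate faces at indices {report.degenerate_face_indices[:10]}"
        )
    if not report.positive_volume:
        raise MeshValidationError(f"{what} has non-positive enclosed volume")


def fix_global_orientation(mesh: TriangleMesh) -> TriangleMesh:
    """Flip all faces when the surface is consistently oriented but inward
    (signed volume < 0). Mixed orientation is never repaired."""
    report = validate_mesh(mesh)
    if report.consistently_oriented and not report.positive_volume:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces[:, ::-1].copy())
    return mesh


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_FORMATS = ("obj", "stl", "ply")


def _format_from_path(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from OBJ, STL (binary or ASCII) or PLY (ASCII).

    Polygonal faces are fan-triangulated. STL per-facet vertices are welded
    under exact coordinate equality. Raises MeshFormatError on parse failure
    and on empty (zero-face) files.
    """
    path = Path(path)
    fmt = _format_from_path(path, fmt)
    if fmt == "obj":
        mesh = _read_obj(path)
    elif fmt == "stl":
        mesh = _read_stl(path)
    else:
        mesh = _read_ply(path)
    if mesh.n_faces == 0:
        raise MeshFormatError(f"{path}: mesh contains no faces")
    return mesh


def _fan(indices: list[int]) -> list[tuple[int, int, int]]:
    return [(indices[0], indices[i], indices[i + 1]) for i in range(1, len(indices) - 1)]


def _read_obj(path: Path) -> TriangleMesh:
    vertices: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: malformed vertex record")
                try:
                    vertices.append([float(parts[1]), float(parts[2]), float(parts[3])])
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
            elif parts[0] == "f":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: face with <3 vertices")
                try:
                    # "v", "v/vt", "v/vt/vn", "v//vn" all begin with the index
                    idx = [int(p.split("/")[0]) for p in parts[1:]]
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
                # OBJ is 1-based; negative indices are relative to the end
                idx = [i - 1 if i > 0 else len(vertices) + i for i in idx]
                if any(i < 0 or i >= len(vertices) for i in idx):
                    raise MeshFormatError(f"{path}:{lineno}: face index out of range")
                faces.extend(_fan(idx))
    return TriangleMesh(np.array(vertices, dtype=float).reshape(-1, 3), np.array(faces, dtype=np.int64).reshape(-1, 3))


def _weld(tri_vertices: np.ndarray) -> TriangleMesh:
    """Weld per-facet vertex records into an indexed mesh under exact
    coordinate equality (deterministic; no tolerance)."""
    flat = tri_vertices.reshape(-1, 3)
    seen: dict[tuple[float, float, float], int] = {}
    index = np.empty(len(flat), dtype=np.int64)
    verts: list[tuple[float, float, float]] = []
    for i, p in enumerate(map(tuple, flat)):
        j = seen.get(p)
        if j is None:
            j = len(verts)
            seen[p] = j
            verts.append(p)
        index[i] = j
    return TriangleMesh(np.array(verts, dtype=float).reshape(-1, 3), index.reshape(-1, 3))


def _read_stl(path: Path) -> TriangleMesh:
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) >= 84:
        (count,) = struct.unpack_from("<I", data, 80)
        if len(data) == 84 + 50 * count and not data[:5].lower().startswith(b"solid"):
            return _read_stl_binary(data, count, path)
        if len(data) == 84 + 50 * count and count > 0:
            # "solid"-prefixed but geometrically consistent binary file
            return _read_stl_binary(data, count, path)
    if data[:5].lower() == b"solid":
        return _read_stl_ascii(data.decode("ascii", errors="replace"), path)
    if len(data) >= 84:
        (count,) = struct.unpack_from("<I", data, 80)
        raise MeshFormatError(
            f"{path}: binary STL record count mismatch "
            f"(header says {count} facets, file holds {(len(data) - 84) // 50})"
        )
    raise MeshFormatError(f"{path}: file too short to be an STL")


def _read_stl_binary(data: bytes, count: int, path: Path) -> TriangleMesh:
    tris = np.frombuffer(data, dtype=np.uint8, count=50 * count, offset=84)
    records = tris.reshape(count, 50)[:, :48].copy().view("<f4").reshape(count, 4, 3)
    tri_vertices = records[:, 1:4, :].astype(float)  # row 0 is the facet normal
    return _weld(tri_vertices)


def _read_stl_ascii(text: str, path: Path) -> TriangleMesh:
    coords: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if parts[:1] == ["vertex"]:
            if len(parts) != 4:
                raise MeshFormatError(f"{path}:{lineno}: malformed vertex line")
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
    if len(coords) % 3 != 0:
        raise MeshFormatError(f"{path}: vertex count {len(coords)} not a multiple of 3")
    return _weld(np.array(coords, dtype=float).reshape(-1, 3, 3))


def _read_ply(path: Path) -> TriangleMesh:
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"{path}: missing 'ply' magic line")
    n_vertices = n_faces = None
    header_end = None
    elements: list[tuple[str, int]] = []
    fmt_ok = False
    for i, line in enumerate(lines[1:], start=1):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            if parts[1] != "ascii":
                raise MeshFormatError(f"{path}: only ASCII PLY is supported")
            fmt_ok = True
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2])))
            if parts[1] == "vertex":
                n_vertices = int(parts[2])
            elif parts[1] == "face":
                n_faces = int(parts[2])
        elif parts[0] == "end_header":
            header_end = i
            break
    if not fmt_ok or header_end is None or n_vertices is None or n_faces is None:
        raise MeshFormatError(f"{path}: incomplete PLY header")

    body = [ln for ln in lines[header_end + 1 :] if ln.strip()]
    if len(body) < n_vertices + n_faces:
        raise MeshFormatError(
            f"{path}: expected {n_vertices + n_faces} body lines, found {len(body)}"
        )
    try:
        vertices = np.array(
            [[float(x) for x in body[i].split()[:3]] for i in range(n_vertices)], dtype=float
        )
    except ValueError as exc:
        raise MeshFormatError(f"{path}: bad vertex line: {exc}") from exc
    faces: list[tuple[int, int, int]] = []
    for i in range(n_vertices, n_vertices + n_faces):
        parts = body[i].split()
        try:
            k = int(parts[0])
            idx = [int(x) for x in parts[1 : 1 + k]]
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{path}: bad face line {i - n_vertices}: {exc}") from exc
        if len(idx) != k or k < 3:
            raise MeshFormatError(f"{path}: bad face line {i - n_vertices}")
        faces.extend(_fan(idx))
    return TriangleMesh(vertices.reshape(-1, 3), np.array(faces, dtype=np.int64).reshape(-1, 3))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a validated mesh to OBJ, binary STL, or ASCII PLY."""
    path = Path(path)
    fmt = _format_from_path(path, fmt)
    require_valid(mesh)
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "stl":
        _write_stl_binary(mesh, path)
    else:
        _write_ply(mesh, path)


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _write_stl_binary(mesh: TriangleMesh, path: Path) -> None:
    header = b"hullbsp binary STL".ljust(80, b"\0")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", mesh.n_faces))
        v = mesh.vertices
        for f in mesh.faces:
            a, b, c = v[f[0]], v[f[1]], v[f[2]]
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            if norm > 0:
                n = n / norm
            fh.write(struct.pack("<12fH", *n, *a, *b, *c, 0))


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------


def make_box(extents, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned box with the given (a, b, c) extents about `center`.
    Volume is exactly a*b*c."""
    extents = np.asarray(extents, dtype=float)
    if np.any(extents <= 0):
        raise ValueError(f"box extents must be positive, got {extents}")
    center = np.asarray(center, dtype=float)
    half = extents / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    vertices = center + corners * half
    # 12 CCW-from-outside triangles over the 8 corners enumerated as
    # (x, y, z) sign triplets in lexicographic order.
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # -x
            [4, 6, 7], [4, 7, 5],  # +x
            [0, 4, 5], [0, 5, 1],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [0, 2, 6], [0, 6, 4],  # -z
            [1, 5, 7], [1, 7, 3],  # +z
        ],
        dtype=np.int64,
    )
    return TriangleMesh(vertices, faces)


_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTICES = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(radius: float, subdivisions: int = 3, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Icosahedron subdivided `subdivisions` times with vertices projected to
    the sphere. Volume converges to (4/3) pi r^3 from below."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    vertices = [v / np.linalg.norm(v) for v in _ICO_VERTICES]
    faces = [tuple(f) for f in _ICO_FACES]
    for _ in range(subdivisions):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            k = midpoint_cache.get(key)
            if k is None:
                m = vertices[i] + vertices[j]
                m = m / np.linalg.norm(m)
                k = len(vertices)
                vertices.append(m)
                midpoint_cache[key] = k
            return k

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
        faces = new_faces
    verts = np.array(vertices, dtype=float) * radius + np.asarray(center, dtype=float)
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def make_prism(length: float, polygon, axis: str = "x", center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Extrude a convex CCW 2D cross-section polygon along a coordinate axis.

    The polygon lies in the plane orthogonal to `axis`; `length` is the
    extrusion extent, centered at `center`. Volume = polygon area * length.
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    polygon = np.asarray(polygon, dtype=float).reshape(-1, 2)
    if len(polygon) < 3:
        raise ValueError("cross-section polygon needs >= 3 vertices")
    area2 = 0.0
    for i in range(len(polygon)):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % len(polygon)]
        area2 += x1 * y2 - x2 * y1
    if area2 <= 0:
        raise ValueError("cross-section polygon must be CCW with positive area")

    axes = {"x": 0, "y": 1, "z": 2}
    if axis not in axes:
        raise ValueError(f"axis must be one of {tuple(axes)}, got {axis!r}")
    k = axes[axis]
    u, w = [i for i in range(3) if i != k]

    n = len(polygon)
    verts = np.zeros((2 * n, 3), dtype=float)
    for side, coord in enumerate((-length / 2.0, length / 2.0)):
        for i, (pu, pw) in enumerate(polygon):
            p = np.zeros(3)
            p[k] = coord
            p[u] = pu
            p[w] = pw
            verts[side * n + i] = p
    verts += np.asarray(center, dtype=float)

    faces: list[tuple[int, int, int]] = []
    # caps: bottom (at -length/2) wound opposite to top
    bottom = list(range(n))
    top = list(range(n, 2 * n))
    # In the (u, w) in-plane frame, the +k cap must be CCW when viewed from +k.
    # (u, w) is a right-handed pair about axis k when (k, u, w) is an even
    # permutation of (0, 1, 2), which holds for the choices above except y.
    flip = k == 1
    top_ring = top if not flip else top[::-1]
    bot_ring = bottom[::-1] if not flip else bottom
    faces.extend(_fan(top_ring))
    faces.extend(_fan(bot_ring))
    for i in range(n):
        j = (i + 1) % n
        a, b = bottom[i], bottom[j]
        c, d = top[i], top[j]
        if not flip:
            faces.extend([(a, b, d), (a, d, c)])
        else:
            faces.extend([(a, d, b), (a, c, d)])
    mesh = TriangleMesh(verts, np.array(faces, dtype=np.int64))
    return fix_global_orientation(mesh)
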