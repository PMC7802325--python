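"""Triangulated-surface primitives: I/O, volume, area, plane splitting, landmarks.

Surfaces stand in for the iso-surface reconstructions exported by commercial
segmentation tools: closed triangle meshes in millimetre units.  Volumes are
computed with the signed-tetrahedron (divergence theorem) formula, which is
exact for any closed, consistently wound triangulation; areas are plain
triangle-area sums.  Both are deliberately implemented here rather than
delegated, so they can be cross-checked against an independent mesh library
in the test-suite.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "Landmark",
    "Plane",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "mesh_volume",
    "mesh_area",
    "split_by_plane",
    "landmark_distance",
    "read_landmarks",
    "write_landmarks",
]

_FORMATS = ("ply", "off", "obj")


class MeshFormatError(ValueError):
    """Raised when a mesh file violates the expected dialect (e.g. quad faces)."""


@dataclass
class Plane:
    """Oriented plane given by a point on it and a unit normal (mm units)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be a finite non-zero vector")
        if abs(norm - 1.0) > 1e-9:
            self.normal = self.normal / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


@dataclass
class Landmark:
    """A named 3D measurement point (mm), e.g. a pupil centre."""

    position: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"landmark {self.label!r} has non-finite coordinates")


@dataclass
class TriMesh:
    """A triangulated surface with consistent winding, coordinates in mm.

    Zero-area faces are dropped at construction; face indices are validated
    against the vertex array.  ``closed`` meshes additionally require every
    edge to be shared by exactly two faces (watertightness).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise ValueError("negative face index")
        areas = _triangle_areas(self.vertices, self.faces)
        keep = areas > 1e-14
        if not np.all(keep):
            self.faces = self.faces[keep]

    # -- basic derived quantities ------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        if "closed" not in self._cache:
            edges = np.sort(
                self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            _, counts = np.unique(edges, axis=0, return_counts=True)
            self._cache["closed"] = bool(len(edges) > 0 and np.all(counts == 2))
        return self._cache["closed"]

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def translated(self, offset) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(offset, float), self.faces, self.name)

    def scaled(self, factor: float) -> "TriMesh":
        return TriMesh(self.vertices * float(factor), self.faces, self.name)


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if len(faces) == 0:
        return np.zeros(0)
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def mesh_area(mesh: TriMesh) -> float:
    """Total surface area (mm^2): sum of triangle areas."""
    return float(_triangle_areas(mesh.vertices, mesh.faces).sum())


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume (mm^3) of a closed mesh via signed tetrahedra.

    Each face spans a tetrahedron with the origin; the signed volumes sum to
    the enclosed volume for outward winding (divergence theorem), making the
    result translation-invariant.  Raises if the mesh is open, or if the
    signed result is negative (inward winding) — the sign is diagnostic and
    is never silently flipped.
    """
    if not mesh.is_closed():
        raise ValueError(f"mesh {mesh.name!r} is not closed")
    tri = mesh.vertices[mesh.faces]
    vol = float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)
    if vol < 0:
        raise ValueError(
            f"mesh {mesh.name!r} has inward winding (signed volume {vol:.6g})"
        )
    return vol


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _scan_triangular(path: Path, fmt: str) -> None:
    """Reject files containing non-triangular faces.

    Generic mesh loaders silently triangulate quads; the measurement
    contract instead requires an explicit format error naming the face.
    Only the ASCII dialects are scanned (binary PLY is handed to the loader
    and validated post-hoc).
    """
    text = path.read_text(errors="replace").splitlines()
    if fmt == "obj":
        face_no = 0
        for line in text:
            parts = line.split()
            if parts and parts[0] == "f":
                if len(parts) - 1 != 3:
                    raise MeshFormatError(
                        f"{path}: face {face_no} has {len(parts) - 1} vertices, expected 3"
                    )
                face_no += 1
    elif fmt == "off":
        body = [ln for ln in text if ln.strip() and not ln.lstrip().startswith("#")]
        if not body or not body[0].strip().upper().startswith("OFF"):
            raise MeshFormatError(f"{path}: missing OFF header")
        header = body[0].strip().split()
        counts = header[1:] if len(header) > 1 else body[1].split()
        start = 1 if len(header) > 1 else 2
        n_vert, n_face = int(counts[0]), int(counts[1])
        for i in range(n_face):
            parts = body[start + n_vert + i].split()
            if int(parts[0]) != 3:
                raise MeshFormatError(
                    f"{path}: face {i} has {parts[0]} vertices, expected 3"
                )
    elif fmt == "ply":
        if not text or text[0].strip() != "ply":
            raise MeshFormatError(f"{path}: missing ply magic")
        if len(text) > 1 and "ascii" not in text[1]:
            return  # binary PLY: loader handles it, invariants checked after
        n_vert = n_face = 0
        end = 0
        for i, line in enumerate(text):
            parts = line.split()
            if parts[:2] == ["element", "vertex"]:
                n_vert = int(parts[2])
            elif parts[:2] == ["element", "face"]:
                n_face = int(parts[2])
            elif parts[:1] == ["end_header"]:
                end = i + 1
                break
        for i in range(n_face):
            parts = text[end + n_vert + i].split()
            if int(parts[0]) != 3:
                raise MeshFormatError(
                    f"{path}: face {i} has {parts[0]} vertices, expected 3"
                )


def read_mesh(path, format: str | None = None, name: str | None = None) -> TriMesh:
    """Read a PLY/OFF/OBJ surface into a :class:`TriMesh` (units taken as mm).

    Non-triangular faces are a format error (reported with the face index),
    not silently triangulated.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected {_FORMATS}")
    _scan_triangular(path, fmt)
    try:
        loaded = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except MeshFormatError:
        raise
    except Exception as exc:  # pragma: no cover - loader specific
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    if loaded.faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: non-triangular faces")
    return TriMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces),
                   name=name or path.stem)


def write_mesh(mesh: TriMesh, path, format: str | None = None) -> Path:
    """Write an ASCII PLY/OFF/OBJ file; deterministic byte output."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    tm = mesh.to_trimesh()
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type=fmt)
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    return path


def read_landmarks(path) -> list[Landmark]:
    """Read landmarks from CSV with header ``label,x,y,z`` (mm units)."""
    path = Path(path)
    out: list[Landmark] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise IOError(f"{path}: landmark CSV needs header columns label,x,y,z")
        for row in reader:
            out.append(
                Landmark([float(row["x"]), float(row["y"]), float(row["z"])],
                         label=row["label"])
            )
    return out


def write_landmarks(landmarks, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z"])
        for lm in landmarks:
            writer.writerow([lm.label, repr(float(lm.position[0])),
                             repr(float(lm.position[1])),
                             repr(float(lm.position[2]))])
    return path


def landmark_distance(a: Landmark, b: Landmark) -> float:
    """Euclidean 3D distance (mm) between two landmarks."""
    return float(np.linalg.norm(a.position - b.position))


# ---------------------------------------------------------------------------
# Plane splitting
# ---------------------------------------------------------------------------


def _ear_clip(loop2d: np.ndarray) -> np.ndarray:
    """Triangulate a simple polygon (CCW or CW) by ear clipping.

    Returns index triples into ``loop2d``.  Handles non-convex cut polygons;
    falls back to fan triangulation if numerical degeneracy exhausts ears.
    """
    n = len(loop2d)
    if n < 3:
        return np.zeros((0, 3), dtype=np.int64)
    # signed area to fix orientation
    x, y = loop2d[:, 0], loop2d[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    order = list(range(n)) if signed >= 0 else list(range(n - 1, -1, -1))
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(order) > 3 and guard < 4 * n * n:
        guard += 1
        m = len(order)
        clipped = False
        for k in range(m):
            i0, i1, i2 = order[k - 1], order[k], order[(k + 1) % m]
            a, b, c = loop2d[i0], loop2d[i1], loop2d[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:  # reflex or degenerate corner
                continue
            # no remaining vertex may lie inside the candidate ear
            ok = True
            for j in order:
                if j in (i0, i1, i2):
                    continue
                p = loop2d[j]
                d0 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                d1 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
                d2 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
                if d0 >= -1e-14 and d1 >= -1e-14 and d2 >= -1e-14:
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                order.pop(k)
                clipped = True
                break
        if not clipped:  # numerically stuck: fan the remainder
            for k in range(1, len(order) - 1):
                tris.append((order[0], order[k], order[k + 1]))
            order = order[:3]
            break
    if len(order) == 3:
        tris.append((order[0], order[1], order[2]))
    return np.asarray(tris, dtype=np.int64)


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of boundary (once-used) edges."""
    edges = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    nxt = {int(a): int(b) for a, b in boundary}
    loops = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            cur = nxt.pop(cur, None)
            if cur is None:  # open chain: degenerate cut, skip
                loop = None
                break
        if loop is not None:
            nxt.pop(start, None)
            if len(loop) >= 3:
                loops.append(np.asarray(loop, dtype=np.int64))
        else:
            nxt.pop(start, None)
    return loops


def _cap(vertices: np.ndarray, faces: np.ndarray, plane: Plane,
         outward: np.ndarray) -> np.ndarray:
    """Close every boundary loop of a cut mesh with an ear-clipped cap.

    ``outward`` is the desired cap normal (pointing out of the kept half)
    so cap winding stays consistent with the body.
    """
    loops = _boundary_loops(faces)
    if not loops:
        return faces
    # orthonormal basis in the cutting plane
    n = outward / np.linalg.norm(outward)
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    new_faces = [faces]
    for loop in loops:
        pts = vertices[loop]
        p2 = np.column_stack([pts @ u, pts @ v])
        tris = _ear_clip(p2)
        if len(tris) == 0:
            continue
        tri_idx = loop[tris]
        # orient each cap triangle along the outward normal
        a, b, c = (vertices[tri_idx[:, 0]], vertices[tri_idx[:, 1]],
                   vertices[tri_idx[:, 2]])
        flip = np.einsum("ij,j->i", np.cross(b - a, c - a), n) < 0
        tri_idx[flip] = tri_idx[flip][:, ::-1]
        new_faces.append(tri_idx)
    return np.vstack(new_faces)


def split_by_plane(mesh: TriMesh, plane: Plane,
                   volume_tolerance: float = 1e-3) -> tuple[TriMesh, TriMesh]:
    """Split a closed mesh by a plane into two closed, capped halves.

    Returns ``(negative_side, positive_side)`` relative to the plane normal.
    Each half is capped across the cut (ear-clipped polygon) so volumes and
    areas remain defined; the two volumes must sum to the original within
    ``volume_tolerance`` (relative) or an error is raised.
    """
    if not mesh.is_closed():
        raise ValueError("split_by_plane requires a closed mesh")
    total = mesh_volume(mesh)
    tm = mesh.to_trimesh()
    halves = []
    for sign in (-1.0, 1.0):
        cut = _trimesh.intersections.slice_mesh_plane(
            tm, plane_normal=sign * plane.normal, plane_origin=plane.point,
            cap=False)
        if cut is None or len(cut.faces) == 0:
            raise ValueError("no intersection: plane misses the mesh")
        cut.merge_vertices()  # slicing duplicates vertices along the cut
        verts = np.asarray(cut.vertices)
        faces = _cap(verts, np.asarray(cut.faces), plane, outward=-sign * plane.normal)
        half = TriMesh(verts, faces, name=f"{mesh.name}_{'neg' if sign < 0 else 'pos'}")
        if not half.is_closed():
            raise ValueError("plane split produced an open half (degenerate cut)")
        halves.append(half)
    v = mesh_volume(halves[0]) + mesh_volume(halves[1])
    if abs(v - total) > volume_tolerance * total:
        raise ValueError(
            f"split volume mismatch: parts {v:.6g} vs whole {total:.6g}")
    return halves[0], halves[1]
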