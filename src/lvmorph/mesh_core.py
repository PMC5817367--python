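"""Mesh data model, standard-format I/O, and generic geometric utilities.

The pipeline works with four containers:

``TriSurface``
    the segmented target geometry of one cardiac frame (triangles, mm);
``QuadMesh``
    one structured quadrilateral surface mesh produced by the morphing;
``Mesh4D``
    a time-ordered sequence of :class:`QuadMesh` frames sharing a single
    connectivity array (1-to-1 vertex correspondence), indexed by the
    nondimensional cycle time ``T`` in ``[0, 1)`` with ``T = 0`` at
    end-diastole;
``Polyline``
    an ordered 3D point chain, the control-point carrier used by the
    bifurcation and connector constructions.

Supported surface formats: STL (ASCII and binary), OBJ, PLY (ASCII) and
legacy VTK polydata, plus whitespace-separated XYZ point clouds.  Vertex
indexing is 0-based internally; exported formats follow their own standard
(OBJ is 1-based).
"""
from __future__ import annotations

import os
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geom import (
    closest_point_on_surface,
    triangle_areas,
    weld_points,
)

WELD_TOL_MM = 1e-6  # below any imaging resolution considered here

__all__ = [
    "TriSurface",
    "QuadMesh",
    "Mesh4D",
    "Polyline",
    "read_surface",
    "read_pointcloud",
    "write_surface",
    "write_mesh",
    "write_mesh4d",
    "read_mesh4d",
    "closed_volume",
    "capped",
    "extract_borders",
    "border_loops_indices",
    "vertex_adjacency",
    "smooth",
    "repair_high_skew",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class TriSurface:
    """Triangle surface with consistent outward orientation."""

    vertices: np.ndarray  # (n, 3) float, mm
    triangles: np.ndarray  # (m, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("TriSurface has non-finite vertex coordinates")
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("TriSurface has out-of-range vertex indices")

    def drop_degenerate(self, tol: float = 1e-12) -> "TriSurface":
        """Remove triangles with area below ``tol`` (mm^2)."""
        areas = triangle_areas(self.vertices, self.triangles)
        return TriSurface(self.vertices, self.triangles[areas > tol])

    @property
    def bbox_diagonal(self) -> float:
        if len(self.vertices) == 0:
            return 0.0
        return float(np.linalg.norm(np.ptp(self.vertices, axis=0)))


@dataclass
class QuadMesh:
    """Structured quadrilateral surface mesh."""

    vertices: np.ndarray  # (n, 3)
    quads: np.ndarray  # (m, 4)
    node_tags: np.ndarray | None = None  # optional per-vertex labels

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.quads = np.asarray(self.quads, dtype=np.int64).reshape(-1, 4)
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("QuadMesh has non-finite vertex coordinates")
        if len(self.quads):
            if self.quads.min() < 0 or self.quads.max() >= len(self.vertices):
                raise ValueError("QuadMesh has out-of-range vertex indices")
            q = np.sort(self.quads, axis=1)
            if np.any(q[:, :-1] == q[:, 1:]):
                raise ValueError("QuadMesh element repeats a vertex")

    def edges(self, directed: bool = False) -> np.ndarray:
        """All element edges, directed as traversed or sorted-undirected."""
        q = self.quads
        e = np.concatenate(
            [q[:, [0, 1]], q[:, [1, 2]], q[:, [2, 3]], q[:, [3, 0]]], axis=0
        )
        return e if directed else np.sort(e, axis=1)

    def triangulated(self) -> TriSurface:
        """Split each quad along its 0-2 diagonal."""
        q = self.quads
        tris = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]], axis=0)
        return TriSurface(self.vertices.copy(), tris)

    def copy(self) -> "QuadMesh":
        tags = None if self.node_tags is None else np.array(self.node_tags)
        return QuadMesh(self.vertices.copy(), self.quads.copy(), tags)


@dataclass
class Mesh4D:
    """Time-ordered quad meshes with one shared connectivity array."""

    frames: list[QuadMesh]
    times: np.ndarray  # nondimensional cycle times T in [0, 1)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.validate()

    def validate(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("Mesh4D needs at least one frame")
        if len(self.times) != len(self.frames):
            raise ValueError("Mesh4D times/frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("Mesh4D times must be strictly increasing")
        q0 = self.frames[0].quads
        for i, f in enumerate(self.frames[1:], start=1):
            if f.quads.shape != q0.shape or not np.array_equal(f.quads, q0):
                raise ValueError(
                    f"frame {i} breaks the 1-to-1 vertex correspondence "
                    "(connectivity differs from frame 0)"
                )

    @property
    def quads(self) -> np.ndarray:
        return self.frames[0].quads

    def positions(self) -> np.ndarray:
        """Stacked vertex positions, shape (n_frames, n_vertices, 3)."""
        return np.stack([f.vertices for f in self.frames], axis=0)


@dataclass
class Polyline:
    """Ordered 3D point chain; if closed, closure is implicit (first != last)."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("Polyline needs at least 2 points")
        if self.closed and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]

    def __len__(self) -> int:
        return len(self.points)

    def lengths(self) -> np.ndarray:
        p = self.points
        seg = np.diff(p, axis=0)
        if self.closed:
            seg = np.vstack([seg, p[0] - p[-1]])
        return np.linalg.norm(seg, axis=1)

    def resample(self, n: int) -> "Polyline":
        """Arc-length uniform resampling to ``n`` points (endpoints kept if open)."""
        p = self.points
        if self.closed:
            p = np.vstack([p, p[0]])
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))])
        total = s[-1]
        if self.closed:
            targets = np.linspace(0.0, total, n, endpoint=False)
        else:
            targets = np.linspace(0.0, total, n)
        out = np.column_stack([np.interp(targets, s, p[:, k]) for k in range(3)])
        return Polyline(out, closed=self.closed)


# ---------------------------------------------------------------------------
# surface I/O
# ---------------------------------------------------------------------------

def _weld_surface(raw_vertices: np.ndarray, raw_tris: np.ndarray) -> TriSurface:
    if len(raw_vertices) == 0:
        raise IOError("surface file contains no geometry")
    uniq, inv = weld_points(raw_vertices, WELD_TOL_MM)
    return TriSurface(uniq, inv[raw_tris]).drop_degenerate()


def _read_stl(path: Path) -> TriSurface:
    data = path.read_bytes()
    is_ascii = data[:5].lower() == b"solid" and b"facet" in data[:1024]
    if is_ascii:
        floats = re.findall(
            rb"vertex\s+([-\d.eE+]+)\s+([-\d.eE+]+)\s+([-\d.eE+]+)", data
        )
        verts = np.array(floats, dtype=float)
    else:
        if len(data) < 84:
            raise IOError(f"truncated STL file: {path}")
        (n_tri,) = struct.unpack("<I", data[80:84])
        body = np.frombuffer(data[84 : 84 + 50 * n_tri], dtype=np.uint8)
        body = body.reshape(n_tri, 50)
        verts = (
            body[:, 12:48].copy().view("<f4").astype(float).reshape(n_tri * 3, 3)
        )
    if len(verts) == 0 or len(verts) % 3:
        raise IOError(f"unreadable or empty STL file: {path}")
    tris = np.arange(len(verts)).reshape(-1, 3)
    return _weld_surface(verts, tris)


def _read_obj(path: Path):
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            faces.append(idx)
    return np.array(verts, dtype=float).reshape(-1, 3), faces


def _read_ply(path: Path):
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise IOError(f"not a PLY file: {path}")
    n_vert = n_face = 0
    i = 0
    for i, line in enumerate(lines):
        t = line.split()
        if t[:2] == ["element", "vertex"]:
            n_vert = int(t[2])
        elif t[:2] == ["element", "face"]:
            n_face = int(t[2])
        elif t and t[0] == "end_header":
            break
    body = lines[i + 1 :]
    verts = np.array(
        [[float(x) for x in body[k].split()[:3]] for k in range(n_vert)]
    )
    faces = []
    for k in range(n_vert, n_vert + n_face):
        t = body[k].split()
        cnt = int(t[0])
        faces.append([int(x) for x in t[1 : 1 + cnt]])
    return verts.reshape(-1, 3), faces


def _read_vtk(path: Path):
    text = path.read_text()
    tokens = text.split()
    verts = []
    faces = []
    i = 0
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "POINTS":
            n = int(tokens[i + 1])
            vals = tokens[i + 3 : i + 3 + 3 * n]
            verts = np.array(vals, dtype=float).reshape(n, 3)
            i += 3 + 3 * n
        elif tok == "POLYGONS":
            n = int(tokens[i + 1])
            i += 3
            for _ in range(n):
                cnt = int(tokens[i])
                faces.append([int(x) for x in tokens[i + 1 : i + 1 + cnt]])
                i += 1 + cnt
        else:
            i += 1
    return np.asarray(verts, dtype=float).reshape(-1, 3), faces


def _faces_to_tris(faces: list[list[int]]) -> np.ndarray:
    tris = []
    for f in faces:
        for k in range(1, len(f) - 1):  # fan triangulation
            tris.append([f[0], f[k], f[k + 1]])
    return np.array(tris, dtype=np.int64).reshape(-1, 3)


_FORMATS = {"stl", "obj", "ply", "vtk"}


def _detect_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported surface format {fmt!r} for {path}")
    return fmt


def read_surface(path: str | os.PathLike, format: str | None = None) -> TriSurface:
    """Read a triangle surface (STL/OBJ/PLY/VTK); quads are fan-triangulated.

    Duplicate vertices are welded at 1e-6 mm and zero-area faces dropped.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"surface file not found: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "stl":
            return _read_stl(path)
        if fmt == "obj":
            verts, faces = _read_obj(path)
        elif fmt == "ply":
            verts, faces = _read_ply(path)
        else:
            verts, faces = _read_vtk(path)
    except (ValueError, IndexError, struct.error) as exc:
        raise IOError(f"unreadable surface file {path}: {exc}") from exc
    if len(verts) == 0 or len(faces) == 0:
        raise IOError(f"empty surface file: {path}")
    if not np.all(np.isfinite(verts)):
        raise IOError(f"non-finite coordinates in surface file: {path}")
    return _weld_surface(verts, _faces_to_tris(faces))


def read_pointcloud(path: str | os.PathLike) -> np.ndarray:
    """Read a whitespace-separated XYZ point cloud."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"point-cloud file not found: {path}")
    pts = np.loadtxt(path, dtype=float, ndmin=2)
    if pts.shape[1] < 3:
        raise IOError(f"point-cloud file {path} has fewer than 3 columns")
    if not np.all(np.isfinite(pts)):
        raise IOError(f"non-finite coordinates in point cloud: {path}")
    return pts[:, :3]


def _faces_of(mesh) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(mesh, QuadMesh):
        return mesh.vertices, mesh.quads
    return mesh.vertices, mesh.triangles


def write_surface(surface: TriSurface, path: str | os.PathLike,
                  format: str | None = None) -> None:
    """Write a triangle surface; same formats as :func:`read_surface`."""
    write_mesh(surface, path, format)


def write_mesh(mesh, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a TriSurface or QuadMesh to STL/OBJ/PLY/VTK (ASCII)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    verts, faces = _faces_of(mesh)
    if fmt == "stl":
        if faces.shape[1] == 4:
            verts, faces = _faces_of(mesh.triangulated())
        with open(path, "w") as fh:
            fh.write("solid lvmorph\n")
            for tri in faces:
                a, b, c = verts[tri]
                n = np.cross(b - a, c - a)
                nl = np.linalg.norm(n)
                n = n / nl if nl > 0 else n
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for p in (a, b, c):
                    fh.write(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid lvmorph\n")
        return
    with open(path, "w") as fh:
        if fmt == "obj":
            for v in verts:
                fh.write(f"v {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            for f in faces:
                fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")
        elif fmt == "ply":
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(verts)}\n"
                "property double x\nproperty double y\nproperty double z\n"
                f"element face {len(faces)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for v in verts:
                fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            for f in faces:
                fh.write(f"{len(f)} " + " ".join(str(i) for i in f) + "\n")
        else:  # vtk legacy polydata
            fh.write("# vtk DataFile Version 3.0\nlvmorph\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {len(verts)} double\n")
            for v in verts:
                fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            k = faces.shape[1]
            fh.write(f"POLYGONS {len(faces)} {len(faces) * (k + 1)}\n")
            for f in faces:
                fh.write(f"{k} " + " ".join(str(i) for i in f) + "\n")


def write_mesh4d(
    mesh4d: Mesh4D,
    directory: str | os.PathLike,
    format: str = "vtk",
    stem: str = "frame",
) -> list[Path]:
    """Write one file per frame, named ``<stem>_t<NN>.<ext>``.

    A sidecar ``<stem>_times.txt`` records the cycle times so the sequence
    round-trips.  Connectivity is identical in every file by construction.
    """
    if len(mesh4d.frames) == 0:
        raise ValueError("cannot write an empty Mesh4D")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(2, len(str(len(mesh4d.frames) - 1)))
    paths = []
    for i, frame in enumerate(mesh4d.frames):
        p = directory / f"{stem}_t{i:0{width}d}.{format}"
        write_mesh(frame, p, format)
        paths.append(p)
    np.savetxt(directory / f"{stem}_times.txt", mesh4d.times)
    return paths


def read_mesh4d(
    directory: str | os.PathLike, format: str = "vtk", stem: str = "frame"
) -> Mesh4D:
    """Read a frame sequence written by :func:`write_mesh4d`."""
    directory = Path(directory)
    paths = sorted(directory.glob(f"{stem}_t*.{format}"))
    if not paths:
        raise IOError(f"no '{stem}_t*.{format}' frames in {directory}")
    frames = []
    for p in paths:
        if format == "stl":
            raise ValueError("STL stores triangles only; cannot round-trip quads")
        if format == "obj":
            verts, faces = _read_obj(p)
        elif format == "ply":
            verts, faces = _read_ply(p)
        else:
            verts, faces = _read_vtk(p)
        quads = np.array(faces, dtype=np.int64)
        if quads.ndim != 2 or quads.shape[1] != 4:
            raise IOError(f"{p} does not contain a pure quad mesh")
        frames.append(QuadMesh(verts, quads))
    tfile = directory / f"{stem}_times.txt"
    if tfile.is_file():
        times = np.loadtxt(tfile).ravel()
    else:
        times = np.arange(len(frames)) / len(frames)
    return Mesh4D(frames, times)


# ---------------------------------------------------------------------------
# geometric utilities
# ---------------------------------------------------------------------------

def _boundary_edges(vertices, faces) -> np.ndarray:
    """Directed boundary edges (used by exactly one face)."""
    k = faces.shape[1]
    directed = np.concatenate(
        [faces[:, [i, (i + 1) % k]] for i in range(k)], axis=0
    )
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    if counts.max(initial=0) > 2:
        raise ValueError("non-manifold edge: used by more than 2 faces")
    return directed[counts[inv] == 1]


def _chain_directed_edges(edges: np.ndarray) -> list[np.ndarray]:
    """Chain directed boundary edges into closed loops of vertex indices."""
    nxt = {}
    for a, b in edges:
        if int(a) in nxt:
            raise ValueError("boundary is not a set of simple loops")
        nxt[int(a)] = int(b)
    loops = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def extract_borders(mesh: QuadMesh) -> list[Polyline]:
    """Closed border loops of a quad mesh, ordered with the mesh orientation.

    Each loop is a maximal chain of edges used by exactly one element; a
    closed mesh yields an empty list.
    """
    edges = _boundary_edges(mesh.vertices, mesh.quads)
    if len(edges) == 0:
        return []
    return [Polyline(mesh.vertices[loop], closed=True)
            for loop in _chain_directed_edges(edges)]


def border_loops_indices(mesh: QuadMesh) -> list[np.ndarray]:
    """Border loops as vertex-index arrays (same order as extract_borders)."""
    edges = _boundary_edges(mesh.vertices, mesh.quads)
    if len(edges) == 0:
        return []
    return _chain_directed_edges(edges)


def capped(surface) -> TriSurface:
    """Triangulated copy of a surface with border loops closed by centroid fans."""
    verts, faces = _faces_of(surface)
    if faces.shape[1] == 4:
        verts, faces = _faces_of(QuadMesh(verts, faces).triangulated())
    boundary = _boundary_edges(verts, faces)
    tris = [faces]
    if len(boundary):
        verts = verts.copy()
        extra = []
        for loop in _chain_directed_edges(boundary):
            centroid = verts[loop].mean(axis=0)
            c_idx = len(verts)
            verts = np.vstack([verts, centroid[None]])
            # fan wound opposite to the boundary direction to close the shell
            for i in range(len(loop)):
                extra.append([loop[(i + 1) % len(loop)], loop[i], c_idx])
        tris.append(np.array(extra, dtype=np.int64))
    return TriSurface(verts, np.concatenate(tris, axis=0))


def tri_border_loops(surface: TriSurface) -> list[Polyline]:
    """Closed border loops of a triangle surface (empty for a closed one)."""
    edges = _boundary_edges(surface.vertices, surface.triangles)
    if len(edges) == 0:
        return []
    return [
        Polyline(surface.vertices[loop], closed=True)
        for loop in _chain_directed_edges(edges)
    ]


def closest_point_on_polyline(points: np.ndarray, poly: Polyline) -> np.ndarray:
    """Nearest point on a polyline (over its segments) for each query point."""
    from ._geom import _point_segment_sq

    p = np.atleast_2d(np.asarray(points, dtype=float))
    a = poly.points
    b = np.roll(poly.points, -1, axis=0) if poly.closed else poly.points[1:]
    if not poly.closed:
        a = poly.points[:-1]
    sq, proj = _point_segment_sq(p[:, None, :], a[None, :, :], b[None, :, :])
    j = np.argmin(sq, axis=1)
    return proj[np.arange(len(p)), j]


def harmonize_orientation(mesh: QuadMesh) -> QuadMesh:
    """Flip elements so every shared edge is traversed in opposite directions.

    Breadth-first over the element adjacency graph; the orientation of the
    first element of each connected component is kept.  Deterministic for a
    fixed connectivity array.
    """
    quads = mesh.quads.copy()
    edge_map: dict[tuple[int, int], list[int]] = {}
    for qi, q in enumerate(quads):
        for k in range(4):
            a, b = int(q[k]), int(q[(k + 1) % 4])
            edge_map.setdefault((min(a, b), max(a, b)), []).append(qi)
    visited = np.zeros(len(quads), dtype=bool)
    for seed in range(len(quads)):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            qi = stack.pop()
            directed = {
                (int(quads[qi][k]), int(quads[qi][(k + 1) % 4])) for k in range(4)
            }
            for k in range(4):
                a, b = int(quads[qi][k]), int(quads[qi][(k + 1) % 4])
                for qj in edge_map[(min(a, b), max(a, b))]:
                    if qj == qi or visited[qj]:
                        continue
                    if (a, b) in {
                        (int(quads[qj][t]), int(quads[qj][(t + 1) % 4]))
                        for t in range(4)
                    }:
                        quads[qj] = quads[qj][::-1]
                    visited[qj] = True
                    stack.append(qj)
    return QuadMesh(mesh.vertices.copy(), quads,
                    None if mesh.node_tags is None else np.array(mesh.node_tags))


def closed_volume(surface, cap_borders: bool = False) -> float:
    """Enclosed volume (mm^3) of a surface by the divergence theorem.

    Signed tetrahedra against the origin are summed and the absolute value
    returned (segmentation tools disagree on orientation).  With
    ``cap_borders`` open border loops are closed by centroid fans before
    integration — the rule used for LV sac volumes, which are open at the
    valve planes.
    """
    verts, faces = _faces_of(surface)
    if faces.shape[1] == 4:
        verts, faces = _faces_of(
            QuadMesh(verts, faces).triangulated()
        )
    if len(_boundary_edges(verts, faces)) and not cap_borders:
        raise ValueError(
            "surface is open; pass cap_borders=True to close border loops"
        )
    closed = capped(TriSurface(verts, faces))
    verts, faces = closed.vertices, closed.triangles
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return abs(float(vol))


def vertex_adjacency(mesh: QuadMesh) -> list[np.ndarray]:
    """Neighbour lists along element edges."""
    n = len(mesh.vertices)
    e = mesh.edges(directed=False)
    e = np.unique(e, axis=0)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for a, b in e:
        neigh[int(a)].append(int(b))
        neigh[int(b)].append(int(a))
    return [np.array(sorted(v), dtype=np.int64) for v in neigh]


def smooth(
    mesh: QuadMesh,
    iterations: int = 10,
    relaxation: float = 0.5,
    frozen_nodes=None,
) -> QuadMesh:
    """Uniform-weight Laplacian smoothing; frozen nodes do not move.

    Connectivity is unchanged.  ``relaxation`` in (0, 1] is the step toward
    the neighbour centroid per iteration.
    """
    if not (0 < relaxation <= 1):
        raise ValueError("relaxation must be in (0, 1]")
    free = np.ones(len(mesh.vertices), dtype=bool)
    if frozen_nodes is not None:
        frozen = np.asarray(list(frozen_nodes), dtype=np.int64)
        if len(frozen) and (frozen.min() < 0 or frozen.max() >= len(free)):
            raise ValueError("frozen_nodes out of range")
        free[frozen] = False
    out = mesh.copy()
    if iterations <= 0 or not free.any():
        return out
    neigh = vertex_adjacency(mesh)
    idx = np.where(free)[0]
    for _ in range(iterations):
        v = out.vertices
        centroids = np.array([v[neigh[i]].mean(axis=0) if len(neigh[i]) else v[i]
                              for i in idx])
        out.vertices[idx] += relaxation * (centroids - v[idx])
    return out


def repair_high_skew(
    mesh: QuadMesh,
    surface: TriSurface,
    max_skew: float = 0.9,
    max_passes: int = 100,
    relaxation: float = 0.5,
) -> tuple[QuadMesh, dict]:
    """Relax and re-project nodes of elements above a skewness threshold.

    Nodes of offending elements are moved toward their neighbour centroid
    and re-projected to the nearest point of ``surface``; repeated until all
    elements pass or ``max_passes`` is reached.  Non-convergence is reported
    in the diagnostics, never raised.
    """
    from .metrics import per_element_skewness  # late import avoids a cycle

    if not (0 < max_skew < 1):
        raise ValueError("max_skew must be in (0, 1)")
    out = mesh.copy()
    neigh = vertex_adjacency(mesh)
    history = []
    converged = False
    for _ in range(max_passes):
        q = per_element_skewness(out.vertices, out.quads)
        history.append(float(q.max()))
        if q.max() <= max_skew:
            converged = True
            break
        bad_nodes = np.unique(out.quads[q > max_skew])
        v = out.vertices
        target = np.array([v[neigh[i]].mean(axis=0) for i in bad_nodes])
        moved = v[bad_nodes] + relaxation * (target - v[bad_nodes])
        _, proj = closest_point_on_surface(moved, surface.vertices, surface.triangles)
        out.vertices[bad_nodes] = proj
    final = per_element_skewness(out.vertices, out.quads)
    diagnostics = {
        "converged": converged,
        "passes": len(history),
        "worst_skew_per_pass": history,
        "final_max_skew": float(final.max()),
    }
    return out, diagnostics
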