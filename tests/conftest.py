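"""Shared geometric fixtures: canonical solids and synthetic targets."""
from __future__ import annotations

import numpy as np
import pytest

from lvmorph.mesh_core import QuadMesh, TriSurface


@pytest.fixture
def cube_tri() -> TriSurface:
    """Unit cube as 12 consistently outward-oriented triangles."""
    v = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    quads = [
        (0, 1, 3, 2),  # x = 0 (inward normal -x)
        (4, 6, 7, 5),  # x = 1
        (0, 4, 5, 1),  # y = 0
        (2, 3, 7, 6),  # y = 1
        (0, 2, 6, 4),  # z = 0
        (1, 5, 7, 3),  # z = 1
    ]
    tris = []
    for a, b, c, d in quads:
        tris.append([a, b, c])
        tris.append([a, c, d])
    return TriSurface(v, np.array(tris))


@pytest.fixture
def cube_quad(cube_tri) -> QuadMesh:
    quads = np.array(
        [
            (0, 1, 3, 2),
            (4, 6, 7, 5),
            (0, 4, 5, 1),
            (2, 3, 7, 6),
            (0, 2, 6, 4),
            (1, 5, 7, 3),
        ]
    )
    return QuadMesh(cube_tri.vertices.copy(), quads)


@pytest.fixture
def octahedron() -> TriSurface:
    v = np.array(
        [
            [1, 0, 0], [-1, 0, 0],
            [0, 1, 0], [0, -1, 0],
            [0, 0, 1], [0, 0, -1],
        ],
        dtype=float,
    )
    tris = np.array(
        [
            [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
            [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
        ]
    )
    return TriSurface(v, tris)


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriSurface:
    """Icosahedron refined by midpoint subdivision, projected to a sphere."""
    phi = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v[0])
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        verts = list(v)
        new_f = []

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = verts[a] + verts[b]
                m = m / np.linalg.norm(m)
                cache[key] = len(verts)
                verts.append(m)
            return cache[key]

        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_f += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.array(verts)
        f = np.array(new_f)
    return TriSurface(v * radius, f)


@pytest.fixture
def sphere10() -> TriSurface:
    return icosphere(radius=10.0, subdivisions=4)


@pytest.fixture
def planar_grid() -> QuadMesh:
    """Flat 6x6 quad grid in the z = 0 plane, unit spacing."""
    n = 6
    xs = np.arange(n + 1, dtype=float)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    quads = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            quads.append([a, a + n + 1, a + n + 2, a + 1])
    return QuadMesh(verts, np.array(quads))


def open_cylinder_quads(
    radius: float = 5.0, height: float = 10.0, n_circ: int = 16, n_ax: int = 4
) -> QuadMesh:
    """Open-ended cylinder quad mesh (two border loops)."""
    verts = []
    for k in range(n_ax + 1):
        z = height * k / n_ax
        ang = 2 * np.pi * np.arange(n_circ) / n_circ
        verts.append(
            np.column_stack(
                [radius * np.cos(ang), radius * np.sin(ang), np.full(n_circ, z)]
            )
        )
    verts = np.vstack(verts)
    quads = []
    for k in range(n_ax):
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            a = k * n_circ
            quads.append([a + j, a + j1, a + n_circ + j1, a + n_circ + j])
    return QuadMesh(verts, np.array(quads))


@pytest.fixture
def cylinder_quads() -> QuadMesh:
    return open_cylinder_quads()
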