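"""Assembly of quad-9 patch complexes into conforming quad meshes.

A patch complex is an array of control points plus, per patch, a 3x3 index
grid ``patch[i, j]`` giving the CP at canonical coordinates
``(u_i, v_j)`` with ``u, v`` in ``{-1, 0, 1}``.  Because the tensor-product
quadratic Lagrange basis restricted to a patch edge depends only on the
three CPs of that edge, two patches sharing an edge (same CP indices)
produce identical subdivided edge nodes, so welding the per-patch lattices
yields a conforming mesh.  The welded topology is computed once, on the
template geometry, and re-evaluated for every frame — this is what makes
the frame-to-frame connectivity byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import weld_points
from .isoparametric import CPSet, PatchGrid, apply, canonical_cps, fit
from .mesh_core import QuadMesh

__all__ = ["grid33_to_cpset", "PatchTopology", "build_topology", "evaluate_frame"]

# canonical CP ordering as (u-index, v-index) pairs into the 3x3 grid:
# corners CCW, edge midpoints CCW, center last
_GRID_ORDER = [
    (0, 0), (2, 0), (2, 2), (0, 2),
    (1, 0), (2, 1), (1, 2), (0, 1),
    (1, 1),
]


def grid33_to_cpset(coords: np.ndarray) -> CPSet:
    """Reorder a (3, 3, 3) CP coordinate grid into the canonical CPSet order."""
    return CPSet(np.array([coords[i, j] for i, j in _GRID_ORDER]))


def _map_one(coords33: np.ndarray, n_sub: int, initial: CPSet) -> np.ndarray:
    t = fit(initial, grid33_to_cpset(coords33))
    return apply(t, PatchGrid(n_sub).nodes)


@dataclass
class PatchTopology:
    """Welded node numbering for a subdivided patch complex."""

    n_sub: int
    quads: np.ndarray  # (n_quads, 4) global vertex indices
    inverse: np.ndarray  # per-patch-lattice-node -> global vertex index
    n_vertices: int


def _instance_nodes(patch_grids: np.ndarray, cps: np.ndarray, n_sub: int) -> np.ndarray:
    initial = canonical_cps(9)
    blocks = [_map_one(cps[g], n_sub, initial) for g in patch_grids]
    return np.concatenate(blocks, axis=0)


def build_topology(
    patch_grids: np.ndarray, cps: np.ndarray, n_sub: int
) -> PatchTopology:
    """Weld subdivided patch lattices (on the given CP geometry) once."""
    nodes = _instance_nodes(patch_grids, cps, n_sub)
    scale = max(float(np.ptp(nodes, axis=0).max()), 1.0)
    _, inverse = weld_points(nodes, 1e-9 * scale)
    per = (n_sub + 1) ** 2
    local_quads = PatchGrid(n_sub).quads
    quads = np.concatenate(
        [inverse[local_quads + p * per] for p in range(len(patch_grids))], axis=0
    )
    return PatchTopology(n_sub, quads, inverse, int(inverse.max()) + 1)


def evaluate_frame(
    topology: PatchTopology, patch_grids: np.ndarray, cps: np.ndarray
) -> QuadMesh:
    """Evaluate all patches on frame CPs and average welded duplicates."""
    nodes = _instance_nodes(patch_grids, cps, topology.n_sub)
    acc = np.zeros((topology.n_vertices, 3))
    cnt = np.zeros(topology.n_vertices)
    np.add.at(acc, topology.inverse, nodes)
    np.add.at(cnt, topology.inverse, 1.0)
    return QuadMesh(acc / cnt[:, None], topology.quads)
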