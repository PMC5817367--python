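"""Quad-4/8/9 isoparametric transformations — the core of the morphing tool.

A quadrilateral patch living in the planar canonical domain
``[-1, 1] x [-1, 1]`` is mapped to 3D by three biquadratic (2nd-order
Lagrangian) polynomials, one per output coordinate::

    x1 = a0 + a1 x + a2 y + a3 x^2 + a4 y^2 + a5 xy + a6 x^2 y + a7 x y^2 + a8 x^2 y^2

(and the same monomial basis with coefficients ``b_n`` for y1 and ``c_n``
for z1).  The coefficients are found by requiring each *initial* control
point (CP) on the patch to map exactly onto its *final* CP, which yields
three small linear systems sharing one monomial matrix.  Quad-4 uses the
bilinear subset of the basis (linear edges), quad-8 drops the ``x^2 y^2``
term (serendipity), quad-9 is the full tensor basis (quadratic edges plus a
face-center CP).

Control-point ordering convention: corners counterclockwise, then edge
midpoints counterclockwise starting from the first edge, then the center
last.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import QuadMesh

__all__ = [
    "CPSet",
    "IsoTransform",
    "PatchGrid",
    "canonical_cps",
    "fit",
    "apply",
    "map_patch",
]

# monomial exponent pairs (i, j) for x^i y^j, per arity
_EXPONENTS = {
    4: [(0, 0), (1, 0), (0, 1), (1, 1)],
    8: [(0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (2, 1), (1, 2)],
    9: [(0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (2, 1), (1, 2), (2, 2)],
}

CONDITION_LIMIT = 1e12


@dataclass
class CPSet:
    """An ordered set of 4, 8 or 9 control points."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.arity not in _EXPONENTS:
            raise ValueError(f"CPSet needs 4, 8 or 9 points, got {len(self.points)}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("CPSet has non-finite coordinates")

    @property
    def arity(self) -> int:
        return len(self.points)


@dataclass
class IsoTransform:
    """Fitted coefficients of one isoparametric transformation."""

    coeffs: np.ndarray  # (arity, 3): columns are a_n, b_n, c_n
    arity: int

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("IsoTransform coefficients are not finite")


@dataclass
class PatchGrid:
    """Regular lattice on the canonical domain [-1,1]^2, z = 0."""

    n_sub: int

    def __post_init__(self):
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")

    @property
    def nodes(self) -> np.ndarray:
        """(n_sub+1)^2 lattice points, row-major in (u, v)."""
        u = np.linspace(-1.0, 1.0, self.n_sub + 1)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        return np.column_stack(
            [uu.ravel(), vv.ravel(), np.zeros(uu.size)]
        )

    @property
    def quads(self) -> np.ndarray:
        n = self.n_sub
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        n00 = i * (n + 1) + j
        return np.column_stack(
            [n00.ravel(), (n00 + (n + 1)).ravel(),
             (n00 + (n + 2)).ravel(), (n00 + 1).ravel()]
        )


def canonical_cps(arity: int = 9) -> CPSet:
    """Initial CPs on the canonical domain in the fixed ordering convention."""
    corners = [(-1, -1), (1, -1), (1, 1), (-1, 1)]
    mids = [(0, -1), (1, 0), (0, 1), (-1, 0)]
    if arity == 4:
        pts = corners
    elif arity == 8:
        pts = corners + mids
    elif arity == 9:
        pts = corners + mids + [(0, 0)]
    else:
        raise ValueError("arity must be 4, 8 or 9")
    return CPSet(np.array([[x, y, 0.0] for x, y in pts]))


def _monomials(points: np.ndarray, arity: int) -> np.ndarray:
    x = points[:, 0]
    y = points[:, 1]
    return np.column_stack([x**i * y**j for i, j in _EXPONENTS[arity]])


def fit(initial: CPSet, final: CPSet) -> IsoTransform:
    """Solve for the transformation coefficients from CP correspondences.

    Three linear systems (one per output coordinate) share the monomial
    matrix of the initial CPs; solved by LU with partial pivoting.  A
    condition number above 1e12 signals degenerate CPs.
    """
    if initial.arity != final.arity:
        raise ValueError(
            f"arity mismatch: initial {initial.arity} vs final {final.arity}"
        )
    m = _monomials(initial.points, initial.arity)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ValueError(
            f"degenerate initial control points (condition number {cond:.3g})"
        )
    coeffs = np.linalg.solve(m, final.points)
    return IsoTransform(coeffs, initial.arity)


def apply(transform: IsoTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the transformation at planar points (z is ignored)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    return _monomials(pts, transform.arity) @ transform.coeffs


def map_patch(final: CPSet, n_sub: int, initial: CPSet | None = None) -> QuadMesh:
    """Map a subdivided canonical patch onto final control points.

    Returns a QuadMesh with ``(n_sub+1)^2`` vertices and ``n_sub^2`` quads;
    the domain corners map exactly onto the final corner CPs.
    """
    if initial is None:
        initial = canonical_cps(final.arity)
    grid = PatchGrid(n_sub)
    t = fit(initial, final)
    return QuadMesh(apply(t, grid.nodes), grid.quads)
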