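"""Temporal densification of a 4D mesh by per-node cubic splines.

Each vertex trajectory is interpolated independently per coordinate over
the nondimensional cycle time ``T`` in ``[0, 1)``, so CFD time-step
requirements can be met regardless of how many frames the imaging dataset
provides.  Two spline kinds:

``natural``
    scipy cubic spline with natural (zero second derivative) end
    conditions, or a periodic spline when the cycle wraps;
``bezier``
    a C1 piecewise-cubic Hermite interpolant with Catmull-Rom style
    finite-difference tangents through the keyframes.

Both reproduce the keyframes exactly; connectivity is copied unchanged, so
the densified sequence keeps the 1-to-1 vertex correspondence.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicHermiteSpline, CubicSpline

from .mesh_core import Mesh4D, QuadMesh

__all__ = ["fit_splines", "interpolate", "resample_at"]

_KINDS = ("natural", "bezier")


def _catmull_rom_tangents(t: np.ndarray, y: np.ndarray, periodic: bool) -> np.ndarray:
    """Finite-difference tangents dy/dt at the keyframes (non-uniform aware)."""
    n = len(t)
    d = np.empty_like(y)
    if periodic:
        # wrap with the true cyclic gaps
        tp = np.concatenate([[t[0] - (t[-1] - t[-2])], t, [t[-1] + (t[1] - t[0])]])
        yp = np.concatenate([y[-2:-1], y, y[1:2]], axis=0)
        for i in range(n):
            d[i] = (yp[i + 2] - yp[i]) / (tp[i + 2] - tp[i])
    else:
        d[0] = (y[1] - y[0]) / (t[1] - t[0])
        d[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
        for i in range(1, n - 1):
            d[i] = (y[i + 1] - y[i - 1]) / (t[i + 1] - t[i - 1])
    return d


def fit_splines(mesh4d: Mesh4D, spline_kind: str = "natural", periodic: bool = False):
    """Fit one vectorised spline over all vertex coordinates.

    Returns a callable ``f(t) -> (n_vertices, 3)`` valid on the keyframe
    span, or on the whole cycle (with wrap-around) when ``periodic``.
    """
    if spline_kind not in _KINDS:
        raise ValueError(f"spline_kind must be one of {_KINDS}")
    times = mesh4d.times
    if len(times) < 3:
        raise ValueError("temporal interpolation needs at least 3 frames")
    if np.any(np.diff(times) <= 0):
        raise ValueError("duplicate or non-increasing frame times")
    pos = mesh4d.positions()  # (F, V, 3)
    if periodic:
        t_ext = np.concatenate([times, [times[0] + 1.0]])
        p_ext = np.concatenate([pos, pos[:1]], axis=0)
        if spline_kind == "natural":
            spl = CubicSpline(t_ext, p_ext, axis=0, bc_type="periodic")
        else:
            tang = _catmull_rom_tangents(times, pos, periodic=True)
            tang = np.concatenate([tang, tang[:1]], axis=0)
            spl = CubicHermiteSpline(t_ext, p_ext, tang, axis=0)
        t0 = times[0]

        def evaluate(t):
            return spl(t0 + np.mod(np.asarray(t, dtype=float) - t0, 1.0))

        return evaluate
    if spline_kind == "natural":
        spl = CubicSpline(times, pos, axis=0, bc_type="natural")
    else:
        tang = _catmull_rom_tangents(times, pos, periodic=False)
        spl = CubicHermiteSpline(times, pos, tang, axis=0)

    def evaluate(t):
        t = np.asarray(t, dtype=float)
        if np.any(t < times[0] - 1e-12) or np.any(t > times[-1] + 1e-12):
            raise ValueError(
                "time outside the keyframe span of a non-periodic sequence"
            )
        return spl(t)

    return evaluate


def interpolate(
    mesh4d: Mesh4D,
    n_intermediate: int,
    spline_kind: str = "natural",
    periodic: bool = False,
) -> Mesh4D:
    """Insert ``n_intermediate`` equally spaced frames in every interval.

    Keyframes are kept (and reproduced exactly, bit-for-bit); when
    ``periodic`` the wrap interval from the last keyframe back to the first
    (at ``T + 1``) is densified too.
    """
    if n_intermediate < 0:
        raise ValueError("n_intermediate must be >= 0")
    if n_intermediate == 0:
        return Mesh4D([f.copy() for f in mesh4d.frames], mesh4d.times.copy())
    evaluate = fit_splines(mesh4d, spline_kind, periodic)
    times = mesh4d.times
    quads = mesh4d.quads
    out_frames: list[QuadMesh] = []
    out_times: list[float] = []
    intervals = len(times) - 1 + (1 if periodic else 0)
    for i in range(intervals):
        t0 = times[i]
        t1 = times[i + 1] if i + 1 < len(times) else times[0] + 1.0
        out_frames.append(mesh4d.frames[i].copy())
        out_times.append(float(t0))
        for k in range(1, n_intermediate + 1):
            t = t0 + (t1 - t0) * k / (n_intermediate + 1)
            out_frames.append(QuadMesh(evaluate(t), quads.copy()))
            out_times.append(float(t))
    if not periodic:
        out_frames.append(mesh4d.frames[-1].copy())
        out_times.append(float(times[-1]))
    return Mesh4D(out_frames, np.asarray(out_times))


def resample_at(
    mesh4d: Mesh4D,
    t: float,
    spline_kind: str = "natural",
    periodic: bool = False,
) -> QuadMesh:
    """Single frame evaluated from the fitted splines at cycle time ``t``."""
    idx = np.where(np.isclose(mesh4d.times, t, atol=1e-12))[0]
    if len(idx):
        return mesh4d.frames[int(idx[0])].copy()
    evaluate = fit_splines(mesh4d, spline_kind, periodic)
    return QuadMesh(evaluate(float(t)), mesh4d.quads.copy())
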