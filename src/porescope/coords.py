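"""Curvilinear centerline coordinates (s, rho, phi) for Cartesian positions.

For a straight centerline the mapping reduces exactly to canonical
cylindrical coordinates; for curved pathways the axial coordinate is the
arc length of the nearest curve point.  Points whose nearest curve point
is an endpoint are assigned ``s`` beyond the fitted range by signed
Euclidean extension along the endpoint tangent, so bulk particles
outside the pore mouths still receive finite coordinates.

The azimuthal angle ``phi`` is measured in [0, 2pi) against a
rotation-minimizing reference normal transported along the curve; it is
meaningful only relatively (it is integrated out in all 1-D profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .centerline import CenterlineSpline

__all__ = ["CurvilinearPosition", "project_point", "to_curvilinear", "map_positions"]


@dataclass(frozen=True)
class CurvilinearPosition:
    """Position in centerline coordinates: arc length, radial distance, angle."""

    s: float  # nm, signed distance along the centerline from the origin
    rho: float  # nm, >= 0, distance from the centerline
    phi: float  # radians in [0, 2pi)

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not 0.0 <= self.phi < 2.0 * np.pi:
            raise ValueError("phi must lie in [0, 2pi)")


def _coarse_s_grid(spline: CenterlineSpline, spacing: float | None) -> np.ndarray:
    if spacing is None:
        knots = spline.s_knots
        spacing = float(np.median(np.diff(knots))) / 4.0 if len(knots) > 1 else 0.025
    n = max(int(np.ceil((spline.s_max - spline.s_min) / spacing)), 8)
    return np.linspace(spline.s_min, spline.s_max, n + 1)


def project_point(spline: CenterlineSpline, q: np.ndarray,
                  coarse_spacing: float | None = None) -> float:
    """Arc-length parameter of the curve point nearest to ``q`` (pore coordinates).

    The global minimum over [s_min, s_max] is located by a coarse scan at
    a quarter of the knot spacing followed by bounded scalar minimization
    on the bracketing interval.
    """
    q = np.asarray(q, dtype=float)
    grid = _coarse_s_grid(spline, coarse_spacing)
    d2 = np.sum((spline(grid) - q) ** 2, axis=1)
    i = int(np.argmin(d2))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi - lo < 1e-12:
        return float(grid[i])
    res = minimize_scalar(
        lambda s: float(np.sum((spline(float(s)) - q) ** 2)),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
    )
    return float(res.x) if res.fun <= d2[i] else float(grid[i])


def to_curvilinear(spline: CenterlineSpline, q: np.ndarray) -> CurvilinearPosition:
    """Map a Cartesian position into (s, rho, phi) centerline coordinates."""
    q = np.asarray(q, dtype=float)
    s_star = project_point(spline, q)
    edge_tol = 1e-7
    at_lo = s_star <= spline.s_min + edge_tol
    at_hi = s_star >= spline.s_max - edge_tol
    if at_lo or at_hi:
        s_end = spline.s_min if at_lo else spline.s_max
        t = spline.tangent(s_end)
        d = q - spline(s_end)
        axial = float(np.dot(d, t))
        # Only extend outward; an interior minimum at the boundary stays put.
        if (at_lo and axial < 0.0) or (at_hi and axial > 0.0):
            s_star = s_end + axial
            radial = d - axial * t
            return _finish(spline, s_end, s_star, radial)
    foot = spline(s_star)
    t = spline.tangent(s_star)
    d = q - foot
    radial = d - float(np.dot(d, t)) * t
    return _finish(spline, s_star, s_star, radial)


def _finish(spline: CenterlineSpline, s_frame: float, s: float, radial: np.ndarray) -> CurvilinearPosition:
    rho = float(np.linalg.norm(radial))
    if rho < 1e-12:
        return CurvilinearPosition(s=s, rho=0.0, phi=0.0)
    n = spline.normal(s_frame)
    t = spline.tangent(s_frame)
    b = np.cross(t, n)
    phi = float(np.arctan2(np.dot(radial, b), np.dot(radial, n))) % (2.0 * np.pi)
    if phi >= 2.0 * np.pi:  # tiny negative angles wrap to exactly 2*pi
        phi = 0.0
    return CurvilinearPosition(s=s, rho=rho, phi=phi)


def map_positions(spline: CenterlineSpline, positions: np.ndarray,
                  polish: bool = False, chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (s, rho) mapping for many positions.

    Uses the coarse scan plus a local quadratic refinement of the squared
    distance (exact for straight centerlines).  With ``polish=True`` each
    point is additionally refined by bounded scalar minimization, as in
    :func:`project_point`.  ``phi`` is not computed here; use
    :func:`to_curvilinear` when the angle is needed.
    """
    positions = np.asarray(positions, dtype=float)
    grid = _coarse_s_grid(spline, None)
    curve_pts = spline(grid)
    tang_lo = spline.tangent(spline.s_min)
    tang_hi = spline.tangent(spline.s_max)
    h = grid[1] - grid[0]

    s_out = np.empty(len(positions))
    rho_out = np.empty(len(positions))
    for start in range(0, len(positions), chunk):
        q = positions[start:start + chunk]
        d2 = np.sum((q[:, None, :] - curve_pts[None, :, :]) ** 2, axis=2)
        i = np.argmin(d2, axis=1)
        s_est = grid[i].astype(float)

        interior = (i > 0) & (i < len(grid) - 1)
        ii = i[interior]
        f_m, f_0, f_p = (d2[interior, ii - 1], d2[interior, ii], d2[interior, ii + 1])
        denom = f_m - 2.0 * f_0 + f_p
        shift = np.where(np.abs(denom) > 1e-300, 0.5 * (f_m - f_p) / np.where(denom == 0, 1, denom), 0.0)
        s_est[interior] += h * np.clip(shift, -1.0, 1.0)

        for j in np.nonzero(~interior)[0]:
            # candidate endpoint extension
            at_lo = i[j] == 0
            s_end = spline.s_min if at_lo else spline.s_max
            t = tang_lo if at_lo else tang_hi
            d = q[j] - spline(s_end)
            axial = float(np.dot(d, t))
            if (at_lo and axial < 0.0) or (not at_lo and axial > 0.0):
                s_est[j] = s_end + axial
            else:
                s_est[j] = project_point(spline, q[j])

        if polish:
            for j in range(len(q)):
                if spline.s_min < s_est[j] < spline.s_max:
                    s_est[j] = project_point(spline, q[j])

        feet = spline(np.clip(s_est, spline.s_min, spline.s_max))
        clipped = np.clip(s_est, spline.s_min, spline.s_max)
        feet = feet + (s_est - clipped)[:, None] * spline.tangent(clipped)
        rho = np.linalg.norm(q - feet, axis=1)
        s_out[start:start + chunk] = s_est
        rho_out[start:start + chunk] = rho
    return s_out, rho_out
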