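"""Continuous centerline curve and profiles along the permeation pathway.

The discrete probe trace is interpolated by a natural cubic spline with
chord-length parameterization and then reparameterized to arc length by
per-segment Gauss-Legendre quadrature with a monotone (PCHIP) inverse
mapping, yielding a unit-speed curve through all probe points.  Scalar
quantities along the pathway are carried as :class:`Profile` objects on
a uniform arc-length grid.

The ``s`` coordinate exposed by :class:`CenterlineSpline` is offset so
that the projection of the initial probe position maps to ``s = 0``,
keeping profiles comparable across trajectory frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .pathway import ProbeTrace, plane_basis

__all__ = [
    "Profile",
    "CenterlineSpline",
    "Mesh",
    "fit_centerline",
    "radius_function",
    "extrude_surface",
    "uniform_grid",
    "rotation_minimizing_normals",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(5)


@dataclass
class Profile:
    """A scalar function of arc length on a uniform grid.

    ``bands`` optionally carries per-grid-point summary statistics
    (mean/sd/min/max over trajectory frames); ``flags`` marks grid
    points whose value is a bound rather than an estimate (dehydrated
    points of free-energy profiles).
    """

    s: np.ndarray  # nm, strictly increasing, uniform spacing
    values: np.ndarray
    quantity: str  # radius | hydrophobicity | density | number_density | free_energy
    bands: dict[str, np.ndarray] | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.s) != len(self.values):
            raise ValueError("grid and values must have the same length")
        if len(self.s) > 1:
            d = np.diff(self.s)
            if np.any(d <= 0):
                raise ValueError("profile grid must be strictly increasing")
            if np.ptp(d) > 1e-9 * max(1.0, abs(d[0])):
                raise ValueError("profile grid must be uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(self.s[1] - self.s[0]) if len(self.s) > 1 else 0.0

    def interp(self, s_query: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation, clamped to edge values outside the grid."""
        return np.interp(s_query, self.s, self.values)

    def to_dict(self) -> dict:
        out = {"quantity": self.quantity, "s": self.s.tolist(), "value": self.values.tolist()}
        if self.bands is not None:
            out["bands"] = {k: np.asarray(v).tolist() for k, v in self.bands.items()}
        if self.flags is not None:
            out["flags"] = np.asarray(self.flags).astype(bool).tolist()
        return out


def uniform_grid(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Uniform grid from ``lo`` covering [lo, hi] with the given spacing."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


class CenterlineSpline:
    """Arc-length-parameterized interpolating cubic spline with attached frames.

    Evaluation uses the pore coordinate ``s`` (arc length minus
    ``s_offset``); queries beyond the fitted range extrapolate linearly
    along the endpoint tangents, so that bulk particles outside the pore
    mouths still receive finite coordinates.
    """

    def __init__(self, curve: CubicSpline, t_fine: np.ndarray, s_fine: np.ndarray,
                 knot_indices: np.ndarray, s_offset: float = 0.0):
        self._curve = curve
        self._dcurve = curve.derivative()
        self._t_fine = t_fine
        self._s_fine = s_fine  # raw arc length at fine nodes, starts at 0
        self._knot_indices = knot_indices
        self._t_of_s = PchipInterpolator(s_fine, t_fine)
        self.s_offset = float(s_offset)
        self._normals_fine: np.ndarray | None = None

    # -- construction ---------------------------------------------------
    @classmethod
    def from_points(cls, points: np.ndarray, subdivisions: int = 16,
                    bc_type: str = "natural", s_offset_index: int | None = None) -> "CenterlineSpline":
        points = np.asarray(points, dtype=float)
        if len(points) < 4:
            raise ValueError(f"centerline interpolation needs at least 4 points, got {len(points)}")
        chords = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(chords == 0):
            raise ValueError("duplicate consecutive points must be merged before fitting")
        t_knots = np.concatenate([[0.0], np.cumsum(chords)])
        curve = CubicSpline(t_knots, points, axis=0, bc_type=bc_type)
        dcurve = curve.derivative()

        # Per-subinterval 5-point Gauss-Legendre arc-length quadrature.
        t_fine = [np.array([0.0])]
        for a, b in zip(t_knots[:-1], t_knots[1:]):
            t_fine.append(np.linspace(a, b, subdivisions + 1)[1:])
        t_fine = np.concatenate(t_fine)
        a = t_fine[:-1]
        h = np.diff(t_fine)
        nodes = a[:, None] + (0.5 * (_GL_NODES + 1.0))[None, :] * h[:, None]
        speeds = np.linalg.norm(dcurve(nodes.ravel()), axis=1).reshape(nodes.shape)
        seg_len = 0.5 * h * (speeds @ _GL_WEIGHTS)
        s_fine = np.concatenate([[0.0], np.cumsum(seg_len)])

        knot_indices = np.arange(0, len(t_fine), subdivisions)
        offset = 0.0
        spline = cls(curve, t_fine, s_fine, knot_indices, offset)
        if s_offset_index is not None:
            spline.s_offset = float(s_fine[knot_indices[s_offset_index]])
        return spline

    # -- coordinate ranges ----------------------------------------------
    @property
    def s_knots(self) -> np.ndarray:
        """Arc-length positions of the interpolated points (pore coordinates)."""
        return self._s_fine[self._knot_indices] - self.s_offset

    @property
    def s_min(self) -> float:
        return -self.s_offset

    @property
    def s_max(self) -> float:
        return float(self._s_fine[-1]) - self.s_offset

    @property
    def length(self) -> float:
        return float(self._s_fine[-1])

    # -- evaluation ------------------------------------------------------
    def _raw(self, s: np.ndarray | float) -> np.ndarray:
        return np.asarray(s, dtype=float) + self.s_offset

    def __call__(self, s: np.ndarray | float) -> np.ndarray:
        """Point on (or linearly extended beyond) the curve at pore coordinate s."""
        raw = np.atleast_1d(self._raw(s))
        clipped = np.clip(raw, 0.0, self.length)
        pts = self._curve(self._t_of_s(clipped))
        over = raw > self.length
        under = raw < 0.0
        if np.any(over):
            pts[over] += (raw[over] - self.length)[:, None] * self.tangent(self.s_max)
        if np.any(under):
            pts[under] += raw[under][:, None] * self.tangent(self.s_min)
        return pts[0] if np.isscalar(s) or np.ndim(s) == 0 else pts

    def tangent(self, s: np.ndarray | float) -> np.ndarray:
        """Unit tangent dS/ds at pore coordinate s (endpoint tangent outside)."""
        raw = np.atleast_1d(np.clip(self._raw(s), 0.0, self.length))
        d = self._dcurve(self._t_of_s(raw))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return d[0] if np.isscalar(s) or np.ndim(s) == 0 else d

    def derivative(self, s: np.ndarray | float) -> np.ndarray:
        """Alias of :meth:`tangent`; the curve is unit-speed by construction."""
        return self.tangent(s)

    # -- transported frame ----------------------------------------------
    def _ensure_normals(self) -> None:
        if self._normals_fine is not None:
            return
        pts = self._curve(self._t_fine)
        tans = self._dcurve(self._t_fine)
        tans = tans / np.linalg.norm(tans, axis=1, keepdims=True)
        n0, _ = plane_basis(tans[0])
        self._normals_fine = rotation_minimizing_normals(pts, tans, n0)

    def normal(self, s: float) -> np.ndarray:
        """Rotation-minimizing reference normal at pore coordinate s.

        The normal is transported from the first grid point, so the
        azimuthal angle defined against it is meaningful only relatively.
        """
        self._ensure_normals()
        raw = float(np.clip(self._raw(s), 0.0, self.length))
        i = int(np.searchsorted(self._s_fine, raw, side="right")) - 1
        i = min(max(i, 0), len(self._s_fine) - 2)
        f = (raw - self._s_fine[i]) / max(self._s_fine[i + 1] - self._s_fine[i], 1e-300)
        n = (1.0 - f) * self._normals_fine[i] + f * self._normals_fine[i + 1]
        t = self.tangent(s if np.isscalar(s) else float(s))
        n = n - np.dot(n, t) * t
        return n / np.linalg.norm(n)


def rotation_minimizing_normals(points: np.ndarray, tangents: np.ndarray, n0: np.ndarray) -> np.ndarray:
    """Transport a reference normal along the curve by the double-reflection method.

    Avoids the frame flips the Frenet frame suffers at inflection points.
    """
    normals = np.empty_like(points)
    n = n0 - np.dot(n0, tangents[0]) * tangents[0]
    normals[0] = n / np.linalg.norm(n)
    for i in range(len(points) - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-300:
            normals[i + 1] = normals[i]
            continue
        n_l = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        t_l = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - t_l
        c2 = np.dot(v2, v2)
        n_next = n_l if c2 < 1e-300 else n_l - (2.0 / c2) * np.dot(v2, n_l) * v2
        n_next = n_next - np.dot(n_next, tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] = n_next / np.linalg.norm(n_next)
    return normals


def _merged_trace(trace: ProbeTrace) -> tuple[np.ndarray, np.ndarray, int]:
    """Drop duplicate consecutive probe points (keeping the first of each run)."""
    points, radii = trace.points, trace.radii
    keep = np.concatenate([[True], np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12])
    if not keep.all():
        warnings.warn(f"merged {np.count_nonzero(~keep)} duplicate consecutive probe point(s)")
    origin = int(np.count_nonzero(keep[: trace.origin_index + 1]) - 1)
    return points[keep], radii[keep], origin


def fit_centerline(trace: ProbeTrace, bc_type: str = "natural") -> CenterlineSpline:
    """Interpolate the probe trace into a unit-speed centerline curve.

    The curve passes through every probe point exactly; the arc-length
    origin is placed at the trace's initial-point slot.
    """
    points, _, origin = _merged_trace(trace)
    return CenterlineSpline.from_points(points, bc_type=bc_type, s_offset_index=origin)


def radius_function(spline: CenterlineSpline, trace: ProbeTrace,
                    spacing: float | None = None) -> Profile:
    """Continuous pore-radius profile: cubic interpolation of (s_i, R_i).

    Evaluated on a uniform grid over the fitted range; the interpolant
    passes through every (s_i, R_i) pair.  Grid spacing defaults to the
    median probe-point arc spacing (the native sweep resolution).
    """
    points, radii, _ = _merged_trace(trace)
    s_knots = spline.s_knots
    if len(s_knots) != len(radii):
        raise ValueError("spline was not fitted from this trace (knot count mismatch)")
    interp = CubicSpline(s_knots, radii, bc_type="natural")
    if spacing is None:
        spacing = float(np.median(np.diff(s_knots)))
    grid = uniform_grid(s_knots[0], s_knots[-1], spacing)
    return Profile(s=grid, values=interp(grid), quantity="radius")


@dataclass
class Mesh:
    """Triangle mesh of the pore surface."""

    vertices: np.ndarray  # (n, 3), nm
    faces: np.ndarray  # (m, 3), int vertex indices

    def to_obj(self) -> str:
        lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in self.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in self.faces]
        return "\n".join(lines) + "\n"


def extrude_surface(spline: CenterlineSpline, radius: Profile, n_ring: int = 16) -> Mesh:
    """Extrude a circular cross section of radius R(s) along the centerline.

    Rings of ``n_ring`` vertices are placed in the plane normal to the
    curve tangent at each grid point, oriented by the rotation-minimizing
    frame, and stitched into a closed tube body.
    """
    if n_ring < 3:
        raise ValueError("n_ring must be at least 3")
    theta = 2.0 * np.pi * np.arange(n_ring) / n_ring
    vertices = np.empty((len(radius.s) * n_ring, 3))
    for k, s in enumerate(radius.s):
        c = spline(float(s))
        t = spline.tangent(float(s))
        n = spline.normal(float(s))
        b = np.cross(t, n)
        ring = c + radius.values[k] * (np.outer(np.cos(theta), n) + np.outer(np.sin(theta), b))
        vertices[k * n_ring:(k + 1) * n_ring] = ring
    faces = []
    for k in range(len(radius.s) - 1):
        base, nxt = k * n_ring, (k + 1) * n_ring
        for j in range(n_ring):
            j1 = (j + 1) % n_ring
            faces.append((base + j, nxt + j, nxt + j1))
            faces.append((base + j, nxt + j1, base + j1))
    return Mesh(vertices=vertices, faces=np.asarray(faces, dtype=int))
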