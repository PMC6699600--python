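"""Permeation-pathway finding by a plane-constrained spherical probe sweep.

A hard-sphere model of the protein is swept by a probe that is advanced
in steps of ``probe_step`` along the channel direction; in each plane
normal to that direction the probe position is optimized with the
downhill simplex (Nelder-Mead) method to maximize the probe radius

    R(P) = min_j ( ||Q_j - P|| - r_j )

over all non-water atoms j.  The sweep terminates once the optimized
radius exceeds ``stop_radius`` (the probe has left the pore); a second
sweep in the opposite direction completes the trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .structure_io import Frame

__all__ = [
    "PathwayConfig",
    "ProbeTrace",
    "HardSphereSet",
    "InitialPointOutsidePoreError",
    "probe_radius",
    "optimize_probe_in_plane",
    "find_pathway",
    "plane_basis",
]


class InitialPointOutsidePoreError(ValueError):
    """The optimized radius at the initial point already exceeds the stop radius."""


@dataclass(frozen=True)
class PathwayConfig:
    """Free parameters of the probe sweep."""

    probe_step: float = 0.1  # nm, plane spacing along the channel direction
    channel_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    initial_point: np.ndarray | None = None  # nm; default: protein center of geometry
    simplex_iterations: int = 100
    stop_radius: float = 1.0  # nm
    max_steps: int = 10000

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_direction", np.asarray(self.channel_direction, dtype=float))
        if self.probe_step <= 0:
            raise ValueError("probe_step must be positive")
        if self.stop_radius <= 0:
            raise ValueError("stop_radius must be positive")
        if abs(np.linalg.norm(self.channel_direction) - 1.0) > 1e-9:
            raise ValueError("channel_direction must be a unit vector (to 1e-9)")


@dataclass
class ProbeTrace:
    """Ordered probe centers and local probe radii from the pathway sweep."""

    points: np.ndarray  # (n, 3), nm, ascending along the channel direction
    radii: np.ndarray  # (n,), nm
    origin_index: int  # slot of the optimized initial point

    def __len__(self) -> int:
        return len(self.radii)

    def validate(self, config: PathwayConfig) -> None:
        if np.any(self.radii <= 0):
            raise ValueError("probe radii must be positive (pore blocked at some plane)")
        if np.any(self.radii > config.stop_radius):
            raise ValueError("accepted probe radii must not exceed the stop radius")
        v = self.points @ config.channel_direction
        steps = np.diff(v)
        if np.any(np.abs(steps - config.probe_step) > 1e-9):
            raise ValueError("consecutive probe points must be spaced by probe_step along the channel direction")


class HardSphereSet:
    """KD-tree-accelerated clearance queries against a set of vdW spheres.

    ``clearance`` is exact: an atom outside the query ball of radius
    ``d_nn - r_nn + r_max`` around P satisfies ``d - r > d_nn - r_nn``
    and therefore cannot attain the minimum, so pruning never changes
    the result with respect to the brute-force minimum.
    """

    def __init__(self, positions: np.ndarray, radii: np.ndarray):
        if len(positions) == 0:
            raise ValueError("hard-sphere set is empty (no protein atoms)")
        if np.any(~np.isfinite(radii)):
            raise ValueError("hard-sphere set requires assigned vdW radii; run assign_vdw_radii first")
        self.positions = np.asarray(positions, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.r_max = float(self.radii.max())
        self._tree = cKDTree(self.positions)

    @classmethod
    def from_frame(cls, frame: Frame) -> "HardSphereSet":
        mask = ~frame.is_water
        return cls(frame.positions[mask], frame.vdw_radii[mask])

    def clearance(self, point: np.ndarray) -> float:
        """min_j(||Q_j - P|| - r_j); negative if the probe overlaps an atom."""
        point = np.asarray(point, dtype=float)
        d_nn, i_nn = self._tree.query(point)
        bound = d_nn - self.radii[i_nn]
        idx = self._tree.query_ball_point(point, bound + self.r_max)
        if not idx:
            return float(bound)
        cand = np.asarray(idx)
        d = np.linalg.norm(self.positions[cand] - point, axis=1)
        return float(np.min(d - self.radii[cand]))

    def clearance_brute_force(self, point: np.ndarray) -> float:
        d = np.linalg.norm(self.positions - np.asarray(point, dtype=float), axis=1)
        return float(np.min(d - self.radii))


def probe_radius(point: np.ndarray, frame: Frame) -> float:
    """Largest probe radius at ``point`` without vdW overlap (may be negative).

    Waters are excluded from the hard-sphere set; the frame must have
    vdW radii assigned.
    """
    return HardSphereSet.from_frame(frame).clearance_brute_force(point)


def plane_basis(channel_direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (e_u, e_w) normal to e_v.

    Gram-Schmidt against the canonical axis least aligned with e_v, so the
    construction is reproducible and well conditioned.
    """
    e_v = np.asarray(channel_direction, dtype=float)
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(e_v)))] = 1.0
    e_u = axis - np.dot(axis, e_v) * e_v
    e_u /= np.linalg.norm(e_u)
    e_w = np.cross(e_v, e_u)
    return e_u, e_w


def optimize_probe_in_plane(
    objective: Frame | HardSphereSet,
    start: np.ndarray,
    e_u: np.ndarray,
    e_w: np.ndarray,
    n_iter: int,
    simplex_scale: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Maximize the probe radius over the plane through ``start`` spanned by e_u, e_w.

    Runs at most ``n_iter`` Nelder-Mead iterations on the 2-D objective
    -R(start + u e_u + w e_w), with an initial simplex of the seed plus two
    vertices offset by ``simplex_scale`` along e_u and e_w and standard
    reflection/expansion/contraction/shrink coefficients (1, 2, 0.5, 0.5).
    The result is never worse than the seed, and lies exactly in the plane.

    ``n_iter = 0`` returns the seed and its probe radius unchanged.
    """
    spheres = objective if isinstance(objective, HardSphereSet) else HardSphereSet.from_frame(objective)
    start = np.asarray(start, dtype=float)
    r_seed = spheres.clearance(start)
    if n_iter <= 0:
        return start, r_seed

    def negative_radius(uw: np.ndarray) -> float:
        return -spheres.clearance(start + uw[0] * e_u + uw[1] * e_w)

    initial_simplex = np.array([[0.0, 0.0], [simplex_scale, 0.0], [0.0, simplex_scale]])
    result = minimize(
        negative_radius,
        x0=np.zeros(2),
        method="Nelder-Mead",
        options={
            "maxiter": n_iter,
            "maxfev": 10 * n_iter + 10,
            "initial_simplex": initial_simplex,
            # effectively iteration-capped: tolerances far below any
            # physically meaningful length (0.1 pm)
            "xatol": 1e-10,
            "fatol": 1e-12,
        },
    )
    if -result.fun < r_seed:  # defensive; the seed is a simplex vertex
        return start, r_seed
    point = start + result.x[0] * e_u + result.x[1] * e_w
    return point, float(-result.fun)


def find_pathway(frame: Frame, config: PathwayConfig | None = None) -> ProbeTrace:
    """Sweep the probe through the pore and return the ordered trace.

    The initial point (default: protein center of geometry) is first
    plane-optimized; the forward sweep then advances by ``probe_step``
    along the channel direction, seeding each plane at the previous
    optimum, until the optimized radius exceeds ``stop_radius``.  A
    reverse sweep in the opposite direction completes the trace, which
    is returned in ascending order along the channel direction.
    """
    if config is None:
        config = PathwayConfig()
    spheres = HardSphereSet.from_frame(frame)
    e_v = config.channel_direction
    e_u, e_w = plane_basis(e_v)
    step = config.probe_step * e_v

    p_init = config.initial_point
    if p_init is None:
        p_init = frame.positions[~frame.is_water].mean(axis=0)
    p0, r0 = optimize_probe_in_plane(spheres, np.asarray(p_init, dtype=float), e_u, e_w, config.simplex_iterations)
    if r0 > config.stop_radius:
        raise InitialPointOutsidePoreError(
            f"optimized probe radius {r0:.3f} nm at the initial point already exceeds the stop radius "
            f"{config.stop_radius:.3f} nm; choose an initial point inside the pore"
        )

    def sweep(direction: np.ndarray) -> tuple[list[np.ndarray], list[float]]:
        points: list[np.ndarray] = []
        radii: list[float] = []
        prev = p0
        for _ in range(config.max_steps):
            seed = prev + direction
            p, r = optimize_probe_in_plane(spheres, seed, e_u, e_w, config.simplex_iterations)
            if r > config.stop_radius:
                return points, radii
            points.append(p)
            radii.append(r)
            prev = p
        warnings.warn("pathway sweep hit max_steps before leaving the pore")
        return points, radii

    fwd_points, fwd_radii = sweep(step)
    rev_points, rev_radii = sweep(-step)

    points = np.array(rev_points[::-1] + [p0] + fwd_points)
    radii = np.array(rev_radii[::-1] + [r0] + fwd_radii)
    trace = ProbeTrace(points=points, radii=radii, origin_index=len(rev_points))
    trace.validate(config)
    return trace
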