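"""Synthetic pore structures with analytic ground truth.

Pseudo-atom pore walls are built as rings of atoms on a radius function
a(z) (optionally along a bent axis), so that every downstream module can
be tested against closed-form or brute-force oracles without any
external structure files.  Wall "residues" carry real amino-acid names
so hydrophobicity tests have meaningful ground truth, and a dedicated
classification fixture places marker residues with known pore-lining /
pore-facing status.

Water placements are generated by rejection sampling against a
prescribed free-energy profile, with linear density proportional to
pi R(s)^2 exp(-beta G(s)), enabling parameter-recovery tests of the
Boltzmann inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import DEFAULT_TEMPERATURE, beta
from .pathway import HardSphereSet
from .structure_io import Frame

__all__ = [
    "FixtureSpec",
    "PoreOracle",
    "make_pore",
    "make_classification_pore",
    "place_waters",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of a synthetic pore.

    ``radius`` is the wall radius a(z) of the cylindrical section (the
    maximum radius for the hourglass); smoothly flaring mouths of length
    ``mouth_length`` (quadratic, curvature ``mouth_curvature``, C1 at the
    junction) are appended at both ends so the probe sweep terminates
    cleanly and a bulk region exists.
    """

    shape: str = "cylinder"  # cylinder | hourglass | funnel | bent
    length: float = 3.0  # nm, interior section
    radius: float = 0.5  # nm
    waist_radius: float = 0.2  # nm (hourglass)
    waist_sigma: float = 0.5  # nm (hourglass)
    mouth_length: float = 0.9  # nm
    mouth_curvature: float = 3.0  # nm^-1
    funnel_slope: float = 0.25  # (funnel shape)
    bend_radius: float = 4.0  # nm (bent shape)
    ring_spacing: float = 0.04  # nm, axial wall-atom spacing
    circumferential_spacing: float = 0.1  # nm
    wall_radius: float = 0.12  # nm, wall-atom vdW radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "hourglass", "funnel", "bent"):
            raise ValueError(f"unknown fixture shape {self.shape!r}")
        if min(self.length, self.radius, self.ring_spacing, self.wall_radius) <= 0:
            raise ValueError("fixture dimensions must be positive")
        a_min = self.waist_radius if self.shape == "hourglass" else self.radius
        if a_min <= self.wall_radius:
            raise ValueError("pore must stay open: a(z) must exceed the wall vdW radius everywhere")

    @property
    def half_extent(self) -> float:
        return self.length / 2.0 + self.mouth_length

    def wall_radius_at(self, z: np.ndarray | float) -> np.ndarray | float:
        """Wall radius a(z) of the (straightened) pore."""
        z = np.asarray(z, dtype=float)
        half = self.length / 2.0
        mouth = 0.5 * self.mouth_curvature * np.maximum(np.abs(z) - half, 0.0) ** 2
        if self.shape in ("cylinder", "bent"):
            a = self.radius + mouth
        elif self.shape == "hourglass":
            a = self.radius - (self.radius - self.waist_radius) * np.exp(-z**2 / (2.0 * self.waist_sigma**2)) + mouth
        elif self.shape == "funnel":
            a = self.radius + self.funnel_slope * (z + half + self.mouth_length) + mouth
        return a


class PoreOracle:
    """Analytic/brute-force ground truth for a generated pore fixture.

    ``s`` is the arc-length coordinate with origin at the projection of
    the protein center of geometry (matching the pathway convention for
    the default initial point).
    """

    def __init__(self, spec: FixtureSpec, frame: Frame, s_ref: float):
        self.spec = spec
        self.frame = frame
        self.s_ref = s_ref  # axis parameter of the s=0 reference
        ds = 2e-3
        self._z_dense = np.arange(-spec.half_extent, spec.half_extent + ds, ds)
        self._a_dense = np.asarray(spec.wall_radius_at(self._z_dense))

    # axis parameterization: u is arc length along the true axis from z=0
    def _axis_angle(self, u: np.ndarray) -> np.ndarray:
        return np.asarray(u, dtype=float) / self.spec.bend_radius

    def centerline(self, s: np.ndarray | float) -> np.ndarray:
        """True centerline point at pore coordinate s."""
        u = np.atleast_1d(np.asarray(s, dtype=float)) + self.s_ref
        if self.spec.shape == "bent":
            theta = self._axis_angle(u)
            rb = self.spec.bend_radius
            pts = np.stack([rb * (np.cos(theta) - 1.0), np.zeros_like(theta), rb * np.sin(theta)], axis=1)
        else:
            pts = np.stack([np.zeros_like(u), np.zeros_like(u), u], axis=1)
        return pts[0] if np.ndim(s) == 0 else pts

    def axis_frame(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(tangent, normal, binormal) of the true axis at pore coordinate s."""
        u = float(s) + self.s_ref
        if self.spec.shape == "bent":
            theta = float(self._axis_angle(u))
            t = np.array([-np.sin(theta), 0.0, np.cos(theta)])
            n = np.array([np.cos(theta), 0.0, np.sin(theta)])
        else:
            t = np.array([0.0, 0.0, 1.0])
            n = np.array([1.0, 0.0, 0.0])
        return t, n, np.cross(t, n)

    def radius(self, s: np.ndarray | float) -> np.ndarray | float:
        """Maximal probe radius on the axis: distance to the continuum wall surface.

        Uses the exact point-to-circle distance for every wall ring of a
        dense axial sample and minimizes over rings; equals a(z) - r_wall
        wherever the wall is locally cylindrical.
        """
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        u = s_arr + self.s_ref
        out = np.empty_like(u)
        if self.spec.shape == "bent":
            rb = self.spec.bend_radius
            theta = self._axis_angle(self._z_dense)
            centers = np.stack([rb * (np.cos(theta) - 1.0), np.zeros_like(theta), rb * np.sin(theta)], axis=1)
            normals = np.stack([np.cos(theta), np.zeros_like(theta), np.sin(theta)], axis=1)
            for k, uk in enumerate(u):
                theta0 = float(self._axis_angle(uk))
                p0 = np.array([rb * (np.cos(theta0) - 1.0), 0.0, rb * np.sin(theta0)])
                d = p0 - centers
                # in-plane/axial split of the point-to-circle distance per ring
                in_n = np.einsum("ij,ij->i", d, normals)
                in_b = d[:, 1]
                rho_ip = np.hypot(in_n, in_b)
                axial2 = np.sum(d * d, axis=1) - rho_ip**2
                out[k] = np.sqrt((rho_ip - self._a_dense) ** 2 + np.maximum(axial2, 0.0)).min()
        else:
            for k, uk in enumerate(u):
                out[k] = np.sqrt(self._a_dense**2 + (self._z_dense - uk) ** 2).min()
        out -= self.spec.wall_radius
        return float(out[0]) if np.ndim(s) == 0 else out

    def interior_band(self, margin: float = 0.3) -> tuple[float, float]:
        """s-interval of the interior (non-mouth) section, shrunk by ``margin``."""
        half = self.spec.length / 2.0
        return (-half + margin - self.s_ref, half - margin - self.s_ref)

    def self_check(self) -> None:
        """Verify the generated wall against the oracle; raise on mismatch.

        Checks that (a) circumferential atom gaps are too narrow for the
        probe to escape, and (b) the hard-sphere clearance on the axis at
        every interior ring plane matches a(z) - r_wall to 1e-6 (exact
        there because a full ring of atoms sits in that plane).
        """
        spec = self.spec
        a_min = spec.waist_radius if spec.shape == "hourglass" else spec.radius
        n_narrow = max(8, int(np.ceil(2.0 * np.pi * a_min / spec.circumferential_spacing)))
        gap = 2.0 * a_min * np.sin(np.pi / n_narrow)
        if gap >= 2.0 * spec.wall_radius:
            raise ValueError("wall atom spacing too coarse: probe could escape between ring atoms")
        if spec.ring_spacing >= 2.0 * spec.wall_radius:
            raise ValueError("wall ring spacing too coarse: probe could escape between rings")
        spheres = HardSphereSet.from_frame(self.frame)
        half = spec.length / 2.0
        z_rings = np.arange(-half + 0.2, half - 0.2 + 1e-9, 5 * spec.ring_spacing)
        # snap to the actual ring levels used at generation time
        z_rings = -spec.half_extent + np.round((z_rings + spec.half_extent) / spec.ring_spacing) * spec.ring_spacing
        # On-axis clearance against the discrete wall can only exceed the
        # continuum oracle, by at most the axial surface-sampling error;
        # where a(z) is locally constant the ring-plane value is exact.
        slack = 1e-6 if spec.shape in ("cylinder", "bent") else spec.ring_spacing**2 / (4.0 * a_min)
        for z in z_rings:
            point = self.centerline(z - self.s_ref) if spec.shape == "bent" else np.array([0.0, 0.0, z])
            expected = float(self.radius(z - self.s_ref))
            got = spheres.clearance(point)
            if not -1e-9 <= got - expected <= slack:
                raise ValueError(
                    f"fixture self-check failed at z={z:.3f}: clearance {got:.8f} vs oracle {expected:.8f}")


def _ring_points(a: float, n: int, phase: float) -> np.ndarray:
    phi = 2.0 * np.pi * np.arange(n) / n + phase
    return np.stack([a * np.cos(phi), a * np.sin(phi)], axis=1)


def make_pore(spec: FixtureSpec) -> tuple[Frame, PoreOracle]:
    """Generate a pseudo-atom pore wall and its analytic oracle.

    Rings of carbon pseudo-atoms are placed on the wall surface a(z) at
    ``ring_spacing`` axial intervals, each ring split into four quadrant
    residues (alanine) so residue bookkeeping is exercised.  vdW radii
    are pre-assigned to ``wall_radius``.  The returned oracle is
    self-checked against the generated wall.
    """
    rng = np.random.default_rng(spec.seed)
    half_ext = spec.half_extent
    z_levels = np.arange(-half_ext, half_ext + 1e-9, spec.ring_spacing)
    positions: list[np.ndarray] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    next_res = 1
    for z in z_levels:
        a = float(spec.wall_radius_at(z))
        n = max(8, int(np.ceil(2.0 * np.pi * a / spec.circumferential_spacing)))
        phase = float(rng.uniform(0.0, 2.0 * np.pi / n))
        ring_xy = _ring_points(a, n, phase)
        if spec.shape == "bent":
            theta = z / spec.bend_radius
            rb = spec.bend_radius
            center = np.array([rb * (np.cos(theta) - 1.0), 0.0, rb * np.sin(theta)])
            nvec = np.array([np.cos(theta), 0.0, np.sin(theta)])
            bvec = np.array([0.0, 1.0, 0.0])
            ring = center + ring_xy[:, :1] * nvec + ring_xy[:, 1:] * bvec
        else:
            ring = np.concatenate([ring_xy, np.full((n, 1), z)], axis=1)
        positions.append(ring)
        quadrant = (np.arange(n) * 4) // n
        res_ids.extend((next_res + quadrant).tolist())
        res_names.extend(["ALA"] * n)
        next_res += 4
    pos = np.concatenate(positions)
    n_atoms = len(pos)
    frame = Frame(
        ids=np.arange(1, n_atoms + 1),
        elements=np.array(["C"] * n_atoms, dtype=object),
        names=np.array(["C"] * n_atoms, dtype=object),
        res_names=np.array(res_names, dtype=object),
        res_ids=np.array(res_ids, dtype=int),
        chains=np.array(["A"] * n_atoms, dtype=object),
        positions=pos,
        is_water=np.zeros(n_atoms, dtype=bool),
        vdw_radii=np.full(n_atoms, spec.wall_radius),
    )
    cog = pos.mean(axis=0)
    if spec.shape == "bent":
        # nearest axis point to the center of geometry (theta = 0 by symmetry)
        s_ref = 0.0
    else:
        s_ref = float(cog[2])
    oracle = PoreOracle(spec, frame, s_ref)
    oracle.self_check()
    return frame, oracle


@dataclass
class ClassificationTruth:
    """Constructed ground truth of the classification fixture."""

    facing: set = field(default_factory=set)  # residue keys (chain, id, name)
    lining_only: set = field(default_factory=set)
    outside: set = field(default_factory=set)

    @property
    def lining(self) -> set:
        return self.facing | self.lining_only


def make_classification_pore(
    spec: FixtureSpec | None = None,
    marker_band: float = 1.0,
    marker_spacing: float = 0.3,
    hydrophobic_band: float = 0.8,
) -> tuple[Frame, PoreOracle, ClassificationTruth]:
    """Cylindrical pore decorated with marker residues of known classification.

    On top of a dense backing wall (glycine pseudo-residues without
    alpha-carbons, which the classifier skips), rings of three-atom
    marker residues are placed at known radial distances:

    - *pore-facing* markers: CA outside two side-chain atoms (side chain
      points inward); leucine within ``hydrophobic_band`` of the midplane
      and glutamate outside it, giving a known hydrophobicity sign pattern;
    - *pore-lining only* markers (serine): CA inside the side chain;
    - *outside* markers (alanine) beyond the lining cutoff.
    """
    if spec is None:
        spec = FixtureSpec(shape="cylinder", length=3.0, radius=0.5)
    frame, oracle = make_pore(spec)
    frame.res_names[:] = "GLY"

    positions = [frame.positions]
    names: list[str] = []
    res_names: list[str] = []
    res_ids: list[int] = []
    truth = ClassificationTruth()
    next_res = int(frame.res_ids.max()) + 1
    new_pos: list[np.ndarray] = []

    def add_residue(res_name: str, atoms: list[tuple[str, float, float, float]]) -> tuple[str, int, str]:
        nonlocal next_res
        key = ("M", next_res, res_name)
        for atom_name, rho, phi, z in atoms:
            new_pos.append(np.array([rho * np.cos(phi), rho * np.sin(phi), z]))
            names.append(atom_name)
            res_names.append(res_name)
            res_ids.append(next_res)
        next_res += 1
        return key

    z_levels = np.arange(-marker_band, marker_band + 1e-9, marker_spacing)
    n_around = 8
    for z in z_levels:
        for j in range(n_around):
            phi = 2.0 * np.pi * j / n_around + (0.1 if z > 0 else 0.0)
            if j % 2 == 0:  # pore-facing: CA farther out than the side chain
                res = "LEU" if abs(z) <= hydrophobic_band else "GLU"
                key = add_residue(res, [("CA", 0.70, phi, z), ("CB", 0.60, phi, z), ("CG", 0.55, phi, z)])
                truth.facing.add(key)
            else:  # pore-lining only: side chain points away from the pore
                key = add_residue("SER", [("CA", 0.55, phi, z), ("CB", 0.70, phi, z), ("OG", 0.75, phi, z)])
                truth.lining_only.add(key)
        for j in range(4):  # outside the lining cutoff entirely
            phi = 2.0 * np.pi * (j + 0.5) / 4
            key = add_residue("ALA", [("CA", 1.60, phi, z), ("CB", 1.65, phi, z), ("CG", 1.70, phi, z)])
            truth.outside.add(key)

    marker_pos = np.array(new_pos)
    n_new = len(marker_pos)
    frame = Frame(
        ids=np.concatenate([frame.ids, np.arange(frame.n_atoms + 1, frame.n_atoms + n_new + 1)]),
        elements=np.concatenate([frame.elements, np.array(["C"] * n_new, dtype=object)]),
        names=np.concatenate([frame.names, np.array(names, dtype=object)]),
        res_names=np.concatenate([frame.res_names, np.array(res_names, dtype=object)]),
        res_ids=np.concatenate([frame.res_ids, np.array(res_ids, dtype=int)]),
        chains=np.concatenate([frame.chains, np.array(["M"] * n_new, dtype=object)]),
        positions=np.concatenate([positions[0], marker_pos]),
        is_water=np.zeros(frame.n_atoms + n_new, dtype=bool),
        vdw_radii=np.concatenate([frame.vdw_radii, np.full(n_new, spec.wall_radius)]),
    )
    oracle = PoreOracle(spec, frame, s_ref=0.0)
    return frame, oracle, truth


def place_waters(
    frame: Frame,
    oracle: PoreOracle,
    target_g: Callable[[np.ndarray], np.ndarray] | None,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    s_range: tuple[float, float] | None = None,
) -> Frame:
    """Append ``n`` water oxygens Boltzmann-consistently with a target G(s).

    Arc positions are drawn by rejection sampling with linear density
    proportional to pi R(s)^2 exp(-beta G(s)) over ``s_range`` (default:
    the full pore extent), uniform over the circular cross section of
    radius R(s).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    spec = oracle.spec
    if s_range is None:
        s_range = (-spec.half_extent - oracle.s_ref, spec.half_extent - oracle.s_ref)
    s_lo, s_hi = s_range

    def g_of(s: np.ndarray) -> np.ndarray:
        return np.zeros_like(s) if target_g is None else np.asarray(target_g(s), dtype=float)

    b = beta(temperature)
    s_dense = np.linspace(s_lo, s_hi, 2048)
    r_dense = np.asarray(oracle.radius(s_dense))
    w_dense = r_dense**2 * np.exp(-b * g_of(s_dense))
    w_max = float(w_dense.max())

    accepted: list[np.ndarray] = []
    n_drawn = 0
    n_accepted = 0
    while n_accepted < n:
        batch = max(4 * (n - n_accepted), 1024)
        s_try = rng.uniform(s_lo, s_hi, batch)
        u = rng.uniform(0.0, w_max, batch)
        r_try = np.interp(s_try, s_dense, r_dense)
        keep = u < r_try**2 * np.exp(-b * g_of(s_try))
        n_drawn += batch
        s_keep = s_try[keep][: n - n_accepted]
        if s_keep.size:
            rho = np.interp(s_keep, s_dense, r_dense) * np.sqrt(rng.uniform(0.0, 1.0, s_keep.size))
            phi = rng.uniform(0.0, 2.0 * np.pi, s_keep.size)
            centers = oracle.centerline(s_keep)
            if spec.shape == "bent":
                theta = (s_keep + oracle.s_ref) / spec.bend_radius
                nvec = np.stack([np.cos(theta), np.zeros_like(theta), np.sin(theta)], axis=1)
                bvec = np.broadcast_to([0.0, 1.0, 0.0], centers.shape)
            else:
                nvec = np.broadcast_to([1.0, 0.0, 0.0], centers.shape)
                bvec = np.broadcast_to([0.0, 1.0, 0.0], centers.shape)
            pts = centers + rho[:, None] * (np.cos(phi)[:, None] * nvec + np.sin(phi)[:, None] * bvec)
            accepted.append(pts)
            n_accepted += s_keep.size
        if n_drawn > 1024 and n_accepted / n_drawn < 1e-4:
            raise ValueError("water placement acceptance rate below 1e-4; rescale the target free energy")

    water_pos = np.concatenate(accepted)
    start_id = int(frame.ids.max()) + 1
    out = Frame(
        ids=np.concatenate([frame.ids, np.arange(start_id, start_id + n)]),
        elements=np.concatenate([frame.elements, np.array(["O"] * n, dtype=object)]),
        names=np.concatenate([frame.names, np.array(["OW"] * n, dtype=object)]),
        res_names=np.concatenate([frame.res_names, np.array(["SOL"] * n, dtype=object)]),
        res_ids=np.concatenate([frame.res_ids, np.arange(1, n + 1)]),
        chains=np.concatenate([frame.chains, np.array(["W"] * n, dtype=object)]),
        positions=np.concatenate([frame.positions, water_pos]),
        is_water=np.concatenate([frame.is_water, np.ones(n, dtype=bool)]),
        vdw_radii=np.concatenate([frame.vdw_radii, np.full(n, 0.152)]),
        time=frame.time,
        box=frame.box,
    )
    return out
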