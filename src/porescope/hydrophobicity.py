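"""Pore-lining/pore-facing residue classification and hydrophobicity profiles.

A residue is *pore-lining* when its center of geometry lies within a
cutoff of the pore surface,

    rho_cog <= R(s_cog) + R_thres            (boundary inclusive),

and a pore-lining residue is *pore-facing* when its alpha-carbon is at
least as far from the centerline as the center of geometry (side chain
pointing inward),

    rho_alpha >= rho_cog                     (boundary inclusive).

Normalized per-residue hydrophobicities are smoothed into a continuous
profile by a Nadaraya-Watson kernel-weighted average with a Gaussian
kernel K(d) = exp(-d^2 / (2 lambda^2)).  The denominator carries a small
constant pseudo-weight K evaluated at 3*lambda so the profile decays to
zero far from any residue instead of locking onto the nearest value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .centerline import CenterlineSpline, Profile
from .coords import to_curvilinear
from .structure_io import Frame

__all__ = [
    "HydrophobicityScale",
    "ResidueAnnotation",
    "GateThermodynamics",
    "BUNDLED_SCALES",
    "normalize_scale",
    "load_scale",
    "classify_residues",
    "hydrophobicity_profile",
    "dewetting_free_energy",
]

#: Names of the bundled scales (two-column files under data/scales/).
BUNDLED_SCALES: tuple[str, ...] = (
    "wimley-white-interface",
    "wimley-white-octanol",
    "kyte-doolittle",
    "hessa",
)

DEFAULT_SCALE = "wimley-white-interface"


@dataclass(frozen=True)
class HydrophobicityScale:
    """A residue hydrophobicity scale with its [-1, +1] normalization.

    Normalized values are oriented so larger means more hydrophobic; the
    most extreme residues reach +1 and/or -1 and a raw value of zero maps
    to normalized zero (the natural zero is preserved).
    """

    name: str
    raw: Mapping[str, float]
    normalized: Mapping[str, float]

    def __getitem__(self, residue_name: str) -> float:
        return self.normalized[residue_name.upper()]

    def __contains__(self, residue_name: str) -> bool:
        return residue_name.upper() in self.normalized


@dataclass
class ResidueAnnotation:
    """Curvilinear coordinates and pore classification of one residue."""

    chain: str
    residue_id: int
    residue_name: str
    s_cog: float  # nm
    rho_cog: float  # nm
    s_alpha: float  # nm
    rho_alpha: float  # nm
    pore_lining: float  # indicator (or time-average ratio in [0, 1])
    pore_facing: float
    hydrophobicity: float = np.nan  # normalized value

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_id, self.residue_name)


@dataclass(frozen=True)
class GateThermodynamics:
    """Liquid-vapor free-energy balance of a cylindrical pore section."""

    radius: float  # nm
    length: float  # nm
    surface_tension: float  # kJ/mol/nm^2
    contact_angle: float  # radians

    @property
    def delta_omega(self) -> float:
        return dewetting_free_energy(self.radius, self.length, self.surface_tension, self.contact_angle)


def normalize_scale(raw: Mapping[str, float], higher_is_hydrophobic: bool = True,
                    name: str = "custom") -> HydrophobicityScale:
    """Two-sided rescale of a raw scale into [-1, +1], preserving the natural zero.

    The sign is flipped first if needed so that larger means more
    hydrophobic; positive values are divided by the largest positive
    value and negative values by the magnitude of the most negative one.
    """
    if not raw:
        raise ValueError("hydrophobicity scale is empty")
    oriented = {k.upper(): (v if higher_is_hydrophobic else -v) for k, v in raw.items()}
    values = np.array(list(oriented.values()))
    if np.all(values == 0):
        raise ValueError("hydrophobicity scale is identically zero; cannot normalize")
    pos_max = values.max()
    neg_min = values.min()
    normalized = {}
    for k, v in oriented.items():
        if v > 0:
            normalized[k] = v / pos_max
        elif v < 0:
            normalized[k] = -v / neg_min  # v/|neg_min|
        else:
            normalized[k] = 0.0
    return HydrophobicityScale(name=name, raw=dict(raw), normalized=normalized)


def load_scale(name_or_path: str) -> HydrophobicityScale:
    """Load a bundled scale by name, or a custom two-column file by path.

    File format: comment lines starting with '#' (a
    ``# higher_is_hydrophobic: true|false`` header sets the raw
    orientation), then ``RESNAME value`` pairs.
    """
    if name_or_path in BUNDLED_SCALES:
        text = resources.files("porescope.data").joinpath(f"scales/{name_or_path}.tsv").read_text()
        name = name_or_path
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise FileNotFoundError(
                f"unknown scale {name_or_path!r}; bundled scales: {', '.join(BUNDLED_SCALES)}")
        text = path.read_text()
        name = path.stem
    higher = True
    raw: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "higher_is_hydrophobic" in line:
                higher = line.split(":", 1)[1].strip().lower() in ("true", "yes", "1")
            continue
        res, value = line.split()
        raw[res.upper()] = float(value)
    return normalize_scale(raw, higher_is_hydrophobic=higher, name=name)


def classify_residues(frame: Frame, spline: CenterlineSpline, radius: Profile,
                      r_thres: float = 0.75,
                      scale: HydrophobicityScale | None = None,
                      cog_atoms: str = "all") -> list[ResidueAnnotation]:
    """Classify every residue as pore-lining and/or pore-facing.

    The residue center of geometry is the unweighted mean of its
    non-hydrogen atoms (``cog_atoms="sidechain"`` restricts it to
    side-chain atoms).  Residues without an alpha-carbon (non-amino-acid
    entities) are excluded with a warning.  If a scale is supplied, each
    annotation carries the residue's normalized hydrophobicity.
    """
    if r_thres <= 0:
        raise ValueError("r_thres must be positive")
    backbone = {"N", "CA", "C", "O", "OXT"}
    annotations: list[ResidueAnnotation] = []
    skipped: list[tuple[str, int, str]] = []
    protein = ~frame.is_water
    for key in frame.residue_keys():
        chain, res_id, res_name = key
        mask = protein & (frame.chains == chain) & (frame.res_ids == res_id) & (frame.res_names == res_name)
        if not mask.any():
            continue
        names = frame.names[mask].astype(str)
        elements = np.char.upper(frame.elements[mask].astype(str))
        positions = frame.positions[mask]
        ca = names == "CA"
        if np.count_nonzero(ca) != 1:
            skipped.append(key)
            continue
        heavy = elements != "H"
        if cog_atoms == "sidechain":
            chosen = heavy & ~np.isin(names, list(backbone))
            if not chosen.any():
                chosen = heavy  # glycine: fall back to whole residue
        else:
            chosen = heavy
        cog = positions[chosen].mean(axis=0)
        cv_cog = to_curvilinear(spline, cog)
        cv_ca = to_curvilinear(spline, positions[ca][0])
        lining = cv_cog.rho <= float(radius.interp(cv_cog.s)) + r_thres
        facing = lining and (cv_ca.rho >= cv_cog.rho)
        h = scale[res_name] if (scale is not None and res_name in scale) else np.nan
        annotations.append(ResidueAnnotation(
            chain=chain, residue_id=res_id, residue_name=res_name,
            s_cog=cv_cog.s, rho_cog=cv_cog.rho, s_alpha=cv_ca.s, rho_alpha=cv_ca.rho,
            pore_lining=float(lining), pore_facing=float(facing), hydrophobicity=h,
        ))
    if skipped:
        warnings.warn(f"excluded {len(skipped)} residue(s) without a unique alpha-carbon")
    return annotations


def hydrophobicity_profile(annotations: Sequence[ResidueAnnotation],
                           grid: np.ndarray,
                           smoothing_span: float = 0.225,
                           facing_only: bool = True) -> Profile:
    """Nadaraya-Watson kernel-smoothed hydrophobicity along the pathway.

    Averages the normalized hydrophobicities of the pore-facing residues
    at their center-of-geometry arc positions with a Gaussian kernel of
    span ``smoothing_span`` (default 0.225 nm, reflecting the axial
    extent of an alpha-helical residue).  A constant pseudo-weight of
    exp(-9/2) in the denominator makes the profile decay to zero far
    from all residues.
    """
    if smoothing_span <= 0:
        raise ValueError("smoothing span must be positive")
    chosen = [a for a in annotations
              if (a.pore_facing > 0 if facing_only else a.pore_lining > 0) and np.isfinite(a.hydrophobicity)]
    if not chosen:
        raise ValueError("no pore-facing residues with hydrophobicity values; cannot build a profile")
    s_i = np.array([a.s_cog for a in chosen])
    h_i = np.array([a.hydrophobicity for a in chosen])
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - s_i[None, :]) / smoothing_span
    kernels = np.exp(-0.5 * z * z)
    w0 = np.exp(-4.5)  # kernel evaluated at 3*lambda
    values = (kernels @ h_i) / (kernels.sum(axis=1) + w0)
    return Profile(s=grid, values=values, quantity="hydrophobicity")


def dewetting_free_energy(radius: float, length: float, surface_tension: float,
                          contact_angle: float) -> float:
    """Free-energy difference between vapor and liquid states of a cylindrical pore.

    delta_omega = 2 pi R gamma_lv (R + L cos theta_e), in kJ/mol for
    gamma_lv in kJ/mol/nm^2 and lengths in nm.  Positive values favor
    the hydrated (liquid) state.
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    return 2.0 * np.pi * radius * surface_tension * (radius + length * np.cos(contact_angle))


def annotation_map(annotations: Sequence[ResidueAnnotation]) -> dict[tuple[str, int], tuple[float, float]]:
    """(chain, residue_id) -> (lining, facing) mapping for the PDB writer."""
    return {(a.chain, a.residue_id): (a.pore_lining, a.pore_facing) for a in annotations}
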