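"""Per-frame analysis composition and aggregation over trajectories.

Each frame is analyzed independently (the pathway sweep is re-run per
frame, and the arc-length origin at the initial probe position keeps
profiles aligned across frames); aggregation computes pointwise summary
statistics — mean, population standard deviation, minimum and maximum —
for every profile quantity, plus time-averaged residue indicators and a
water-density heatmap (frames x s-grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np

from .centerline import CenterlineSpline, Profile, fit_centerline, radius_function
from .hydrophobicity import (
    DEFAULT_SCALE,
    HydrophobicityScale,
    ResidueAnnotation,
    classify_residues,
    hydrophobicity_profile,
    load_scale,
)
from .pathway import PathwayConfig, ProbeTrace, find_pathway
from .solvent import KdeConfig, SolventProfiles, analyze_solvent
from .structure_io import Frame

__all__ = ["AnalysisConfig", "FrameResult", "ProfileSeries", "AggregateResult", "analyze_frame", "aggregate"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to analyze one frame."""

    pathway: PathwayConfig = dataclass_field(default_factory=PathwayConfig)
    kde: KdeConfig = dataclass_field(default_factory=lambda: KdeConfig())
    r_thres: float = 0.75  # nm, pore-lining cutoff
    scale: str | HydrophobicityScale = DEFAULT_SCALE
    smoothing_span: float = 0.225  # nm
    bulk_band: Sequence[tuple[float, float]] | tuple[float, float] | None = None
    dewet_fraction: float = 0.2
    dewet_min_length: float = 0.3  # nm
    grid_spacing: float | None = None  # default: probe step
    with_solvent: bool = True

    def resolved_scale(self) -> HydrophobicityScale:
        return self.scale if isinstance(self.scale, HydrophobicityScale) else load_scale(self.scale)


@dataclass
class FrameResult:
    """All per-frame outputs of the annotation pipeline."""

    time: float
    trace: ProbeTrace
    spline: CenterlineSpline
    radius: Profile
    hydrophobicity: Profile | None
    annotations: list[ResidueAnnotation]
    solvent: SolventProfiles | None


@dataclass
class ProfileSeries:
    """Per-frame profile values on a common grid with summary statistics."""

    quantity: str
    s: np.ndarray
    values: np.ndarray  # (n_frames, n_grid), NaN where a frame does not cover s
    times: np.ndarray  # ps

    def _stat(self, fn) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return fn(self.values, axis=0)

    @property
    def mean(self) -> np.ndarray:
        return self._stat(np.nanmean)

    @property
    def sd(self) -> np.ndarray:
        """Population (1/n) standard deviation over frames."""
        return self._stat(np.nanstd)

    @property
    def min(self) -> np.ndarray:
        return self._stat(np.nanmin)

    @property
    def max(self) -> np.ndarray:
        return self._stat(np.nanmax)

    def summary_profile(self) -> Profile:
        return Profile(s=self.s, values=self.mean, quantity=self.quantity,
                       bands={"mean": self.mean, "sd": self.sd, "min": self.min, "max": self.max})


@dataclass
class AggregateResult:
    series: dict[str, ProfileSeries]
    annotations: dict[tuple[str, int, str], tuple[float, float]]  # key -> (lining, facing) time averages
    density_matrix: np.ndarray | None  # (n_frames, n_grid) water number density
    times: np.ndarray


def analyze_frame(frame: Frame, config: AnalysisConfig | None = None) -> FrameResult:
    """Run the full single-frame pipeline: pathway, centerline, profiles, residues."""
    if config is None:
        config = AnalysisConfig()
    trace = find_pathway(frame, config.pathway)
    spline = fit_centerline(trace)
    spacing = config.grid_spacing if config.grid_spacing is not None else config.pathway.probe_step
    radius = radius_function(spline, trace, spacing=spacing)

    scale = config.resolved_scale()
    annotations = classify_residues(frame, spline, radius, r_thres=config.r_thres, scale=scale)
    try:
        hydro = hydrophobicity_profile(annotations, radius.s, smoothing_span=config.smoothing_span)
    except ValueError:
        hydro = None  # no classifiable pore-facing residues in this structure

    solvent = None
    if config.with_solvent and bool(frame.is_water.any()):
        solvent = analyze_solvent(
            frame, spline, radius, config=config.kde, bulk_band=config.bulk_band,
            dewet_fraction=config.dewet_fraction, dewet_min_length=config.dewet_min_length,
        )
    return FrameResult(time=frame.time, trace=trace, spline=spline, radius=radius,
                       hydrophobicity=hydro, annotations=annotations, solvent=solvent)


def _resample(profile: Profile, grid: np.ndarray) -> np.ndarray:
    """Linear resampling onto the common grid; NaN outside the profile's range."""
    values = np.interp(grid, profile.s, profile.values, left=np.nan, right=np.nan)
    return values


def aggregate(results: Sequence[FrameResult],
              grid: np.ndarray | None = None) -> AggregateResult:
    """Pointwise summary statistics over frames for every available quantity.

    Profiles are resampled onto a common grid (default: the grid of the
    first frame's radius profile).  The density matrix rows follow frame
    order; aggregation itself is permutation-invariant.
    """
    if not results:
        raise ValueError("aggregate requires at least one frame result")
    if grid is None:
        grid = results[0].radius.s
    times = np.array([r.time for r in results])

    def collect(select) -> np.ndarray | None:
        rows = []
        for r in results:
            p = select(r)
            rows.append(_resample(p, grid) if p is not None else np.full(len(grid), np.nan))
        mat = np.array(rows)
        return mat if np.any(np.isfinite(mat)) else None

    series: dict[str, ProfileSeries] = {}
    quantities = {
        "radius": lambda r: r.radius,
        "hydrophobicity": lambda r: r.hydrophobicity,
        "density": lambda r: r.solvent.probability if r.solvent else None,
        "number_density": lambda r: r.solvent.number_density if r.solvent else None,
        "free_energy": lambda r: r.solvent.free_energy if r.solvent else None,
    }
    for quantity, select in quantities.items():
        mat = collect(select)
        if mat is not None:
            series[quantity] = ProfileSeries(quantity=quantity, s=grid, values=mat, times=times)

    keys = sorted({a.key for r in results for a in r.annotations})
    lining = {k: 0.0 for k in keys}
    facing = {k: 0.0 for k in keys}
    for r in results:
        for a in r.annotations:
            lining[a.key] += a.pore_lining
            facing[a.key] += a.pore_facing
    n = len(results)
    annotations = {k: (lining[k] / n, facing[k] / n) for k in keys}

    density_matrix = series["number_density"].values if "number_density" in series else None
    return AggregateResult(series=series, annotations=annotations,
                           density_matrix=density_matrix, times=times)
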