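"""Read/write structural data and assign van der Waals radii.

Structures are held as :class:`Frame` objects, a structure-of-arrays
container with one entry per atom.  Coordinates are stored in nm; the
fixed-width PDB columns are converted from/to Angstrom at the boundary.

PDB I/O is implemented directly against the fixed-width column layout
(ATOM/HETATM/MODEL/ENDMDL; occupancy columns 55-60, B-factor columns
61-66) so that parse errors can name the offending line and so that the
annotation writer has exact control over the occupancy/B-factor fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from .constants import NM_PER_ANGSTROM

__all__ = [
    "Atom",
    "Frame",
    "VdwRadiusTable",
    "PdbFormatError",
    "DEFAULT_WATER_NAMES",
    "read_structure",
    "write_structure",
    "write_annotated_pdb",
    "assign_vdw_radii",
]

#: Residue names recognised as water (configurable in :func:`read_structure`).
DEFAULT_WATER_NAMES: tuple[str, ...] = ("HOH", "SOL", "WAT", "TIP3", "TIP3P", "TIP4", "SPC")

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "CA", "SE", "SI", "AL", "LI", "RB", "CS",
}


class PdbFormatError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


class Atom(NamedTuple):
    """Read-only per-atom view into a :class:`Frame`."""

    id: int
    element: str
    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray  # (3,), nm
    vdw_radius: float  # nm, NaN until assigned
    is_water: bool


@dataclass
class Frame:
    """One structural configuration: atoms with coordinates and metadata.

    Arrays all have length ``n_atoms``.  ``vdw_radii`` is NaN until
    :func:`assign_vdw_radii` has been applied.
    """

    ids: np.ndarray
    elements: np.ndarray
    names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chains: np.ndarray
    positions: np.ndarray  # (n, 3), nm
    is_water: np.ndarray
    vdw_radii: np.ndarray = field(default=None)  # type: ignore[assignment]
    time: float = 0.0  # ps
    box: np.ndarray | None = None  # (3,), nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.vdw_radii is None:
            self.vdw_radii = np.full(len(self.positions), np.nan)
        self.is_water = np.asarray(self.is_water, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                int(self.ids[i]), str(self.elements[i]), str(self.names[i]),
                str(self.res_names[i]), int(self.res_ids[i]), str(self.chains[i]),
                self.positions[i], float(self.vdw_radii[i]), bool(self.is_water[i]),
            )

    def validate(self) -> None:
        """Check frame invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom coordinates")
        if np.all(self.is_water):
            raise ValueError("frame contains no non-water atoms")
        if len(np.unique(self.ids)) != self.n_atoms:
            raise ValueError("atom ids are not unique within the frame")
        assigned = ~np.isnan(self.vdw_radii)
        if np.any(self.vdw_radii[assigned] <= 0):
            raise ValueError("assigned vdW radii must be positive")

    def copy(self) -> "Frame":
        return Frame(
            ids=self.ids.copy(), elements=self.elements.copy(), names=self.names.copy(),
            res_names=self.res_names.copy(), res_ids=self.res_ids.copy(),
            chains=self.chains.copy(), positions=self.positions.copy(),
            is_water=self.is_water.copy(), vdw_radii=self.vdw_radii.copy(),
            time=self.time, box=None if self.box is None else self.box.copy(),
        )

    def subset(self, mask: np.ndarray) -> "Frame":
        return Frame(
            ids=self.ids[mask], elements=self.elements[mask], names=self.names[mask],
            res_names=self.res_names[mask], res_ids=self.res_ids[mask],
            chains=self.chains[mask], positions=self.positions[mask],
            is_water=self.is_water[mask], vdw_radii=self.vdw_radii[mask],
            time=self.time, box=self.box,
        )

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_id, residue_name) keys in first-seen order."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, rid, rn in zip(self.chains, self.res_ids, self.res_names):
            seen.setdefault((str(c), int(rid), str(rn)), None)
        return list(seen)


@dataclass(frozen=True)
class VdwRadiusTable:
    """Lookup table from (residue, atom name) or element to a vdW radius in nm.

    Lookup precedence: (residue_name, atom_name) > element > default.
    """

    by_element: Mapping[str, float]
    by_name: Mapping[tuple[str, str], float] = field(default_factory=dict)
    default_radius: float | None = None

    def __post_init__(self) -> None:
        for r in list(self.by_element.values()) + list(self.by_name.values()):
            if not 0.05 < r < 0.35:
                raise ValueError(f"vdW radius {r} nm outside plausible range (0.05, 0.35)")

    def lookup(self, element: str, name: str = "", residue_name: str = "") -> float | None:
        key = (residue_name.upper(), name.upper())
        if key in self.by_name:
            return self.by_name[key]
        return self.by_element.get(element.upper(), self.default_radius)

    @classmethod
    def from_lines(cls, lines: Iterable[str], default_radius: float | None = 0.15) -> "VdwRadiusTable":
        by_element: dict[str, float] = {}
        by_name: dict[tuple[str, str], float] = {}
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                by_element[parts[0].upper()] = float(parts[1])
            elif len(parts) == 3:
                by_name[(parts[0].upper(), parts[1].upper())] = float(parts[2])
            else:
                raise ValueError(f"malformed radius-table line: {line!r}")
        return cls(by_element=by_element, by_name=by_name, default_radius=default_radius)

    @classmethod
    def default(cls) -> "VdwRadiusTable":
        """Bundled element radii (Bondi 1964 set), default 0.15 nm for unknowns."""
        text = resources.files("porescope.data").joinpath("vdw_radii.tsv").read_text()
        return cls.from_lines(text.splitlines())


def _guess_element(name: str) -> str:
    alpha = "".join(ch for ch in name if ch.isalpha()).upper()
    if len(alpha) >= 2 and alpha[:2] in _TWO_LETTER_ELEMENTS:
        return alpha[:2]
    return alpha[:1] if alpha else ""


def _parse_atom_line(line: str, lineno: int) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"unparseable ATOM/HETATM record on line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return serial, name, res_name, chain, res_id, (x, y, z), element


def read_structure(
    pdb_text: str,
    water_names: Sequence[str] = DEFAULT_WATER_NAMES,
) -> list[Frame]:
    """Parse PDB-format text into one :class:`Frame` per model.

    Structures without MODEL records yield a single frame.  Coordinates
    are converted from Angstrom to nm.  Waters are identified by residue
    name (``water_names``, case-insensitive).

    Raises
    ------
    PdbFormatError
        If an ATOM/HETATM record cannot be parsed (names the line) or if
        the text contains no atoms.
    """
    water_set = {w.upper() for w in water_names}
    frames: list[Frame] = []
    box: np.ndarray | None = None
    records: list[tuple] = []

    def _flush(time_index: int) -> None:
        nonlocal records
        if not records:
            return
        serials, names, res_names, chains, res_ids, xyz, elements = zip(*records)
        positions = np.asarray(xyz, dtype=float) * NM_PER_ANGSTROM
        is_water = np.array([rn.upper() in water_set for rn in res_names])
        frames.append(Frame(
            ids=np.asarray(serials, dtype=int),
            elements=np.asarray(elements, dtype=object),
            names=np.asarray(names, dtype=object),
            res_names=np.asarray(res_names, dtype=object),
            res_ids=np.asarray(res_ids, dtype=int),
            chains=np.asarray(chains, dtype=object),
            positions=positions,
            is_water=is_water,
            time=float(time_index),
            box=box,
        ))
        records = []

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6].strip()
        if record in ("ATOM", "HETATM"):
            records.append(_parse_atom_line(line, lineno))
        elif record in ("MODEL", "ENDMDL"):
            _flush(len(frames))
        elif record == "CRYST1":
            try:
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])]) * NM_PER_ANGSTROM
            except (ValueError, IndexError):
                warnings.warn(f"ignoring malformed CRYST1 record on line {lineno}")
    _flush(len(frames))

    if not frames:
        raise PdbFormatError("no atoms found in PDB input")
    return frames


def _format_atom_line(
    record: str, serial: int, name: str, res_name: str, chain: str, res_id: int,
    position_nm: np.ndarray, occupancy: float, b_factor: float, element: str,
) -> str:
    # PDB atom-name convention: names shorter than 4 chars start in column 14.
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    x, y, z = np.asarray(position_nm) / NM_PER_ANGSTROM
    return (
        f"{record:<6s}{serial % 100000:>5d} {name_field:<4.4s} {res_name:>3.3s} "
        f"{chain[:1]}{res_id % 10000:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{b_factor:6.2f}          {element:>2.2s}"
    )


def write_structure(
    frames: Frame | Sequence[Frame],
    occupancies: np.ndarray | None = None,
    b_factors: np.ndarray | None = None,
) -> str:
    """Serialize one or more frames as PDB text (MODEL blocks if several)."""
    if isinstance(frames, Frame):
        frames = [frames]
    lines: list[str] = []
    multi = len(frames) > 1
    for model_no, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {model_no:>4d}")
        occ = occupancies if occupancies is not None else np.ones(frame.n_atoms)
        bf = b_factors if b_factors is not None else np.zeros(frame.n_atoms)
        for i in range(frame.n_atoms):
            record = "HETATM" if frame.is_water[i] else "ATOM"
            lines.append(_format_atom_line(
                record, int(frame.ids[i]), str(frame.names[i]), str(frame.res_names[i]),
                str(frame.chains[i]), int(frame.res_ids[i]), frame.positions[i],
                float(occ[i]), float(bf[i]), str(frame.elements[i]),
            ))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_annotated_pdb(
    frame: Frame,
    annotations: Mapping[tuple[str, int], tuple[float, float]],
) -> str:
    """Write a PDB with per-residue indicators in the occupancy/B-factor fields.

    ``annotations`` maps (chain, residue_id) to a (pore_lining, pore_facing)
    pair; for trajectories these are time averages in [0, 1].  The
    pore-lining indicator goes to the occupancy column, the pore-facing
    indicator to the B-factor column.  Residues absent from ``annotations``
    default to (0, 0) with a warning.
    """
    occ = np.zeros(frame.n_atoms)
    bf = np.zeros(frame.n_atoms)
    missing: set[tuple[str, int]] = set()
    for i in range(frame.n_atoms):
        key = (str(frame.chains[i]), int(frame.res_ids[i]))
        if key in annotations:
            lining, facing = annotations[key]
            occ[i], bf[i] = float(lining), float(facing)
        elif not frame.is_water[i]:
            missing.add(key)
    if missing:
        warnings.warn(f"{len(missing)} residue(s) without annotation written as 0.00")
    return write_structure(frame, occupancies=occ, b_factors=bf)


def assign_vdw_radii(frame: Frame, table: VdwRadiusTable | None = None) -> Frame:
    """Return a copy of ``frame`` with vdW radii assigned to every non-water atom.

    Lookup precedence is (residue_name, atom_name) > element > table default.
    Waters receive a radius when their element resolves but are never part
    of the hard-sphere set used by the pathway sweep.

    Raises
    ------
    LookupError
        If any non-water atom has no matching entry and the table carries
        no default radius; the message lists the offending atoms.
    """
    if table is None:
        table = VdwRadiusTable.default()
    radii = np.full(frame.n_atoms, np.nan)
    unresolved: list[str] = []
    for i in range(frame.n_atoms):
        r = table.lookup(str(frame.elements[i]), str(frame.names[i]), str(frame.res_names[i]))
        if r is None:
            if not frame.is_water[i]:
                unresolved.append(f"{frame.chains[i]}/{frame.res_names[i]}{frame.res_ids[i]}:{frame.names[i]}")
        else:
            radii[i] = r
    if unresolved:
        shown = ", ".join(unresolved[:10]) + ("..." if len(unresolved) > 10 else "")
        raise LookupError(f"no vdW radius for {len(unresolved)} atom(s) and no default set: {shown}")
    return replace(frame.copy(), vdw_radii=radii)
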