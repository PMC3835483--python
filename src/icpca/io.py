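"""Structure, ensemble, charge and energy-table I/O.

All readers return plain in-memory containers; no science happens here.
Coordinates are Angstrom throughout (XYZ and PDB are Angstrom by
convention; no unit auto-detection). Atom indices are 0-based in memory
and 1-based in every file written or read.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES, TWO_LETTER_ELEMENTS, element_mass
from .errors import AlignmentError, FormatError, SchemaError

__all__ = [
    "Structure",
    "Ensemble",
    "ChargeSet",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "read_pdb_ensemble",
    "write_pdb",
    "read_charges",
    "write_pqr",
    "read_energy_table",
    "write_energy_table",
    "infer_element",
]

#: mandatory columns of a per-frame energy table
ENERGY_REQUIRED = ("kinetic", "potential")
ENERGY_OPTIONAL = ("bond", "angle", "urey_bradley", "dihedral")


@dataclasses.dataclass
class Structure:
    """One conformation: atom metadata plus a single coordinate frame."""

    labels: list[str]
    elements: list[str]
    masses: np.ndarray  # (n,) amu
    coords: np.ndarray  # (n, 3) Angstrom

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.labels)
        if not (len(self.elements) == self.masses.shape[0] == n):
            raise FormatError("atom metadata lengths disagree")
        if self.coords.shape != (n, 3):
            raise FormatError(
                f"coordinate array has shape {self.coords.shape}, expected ({n}, 3)"
            )
        if np.any(self.masses <= 0):
            raise FormatError("masses must be strictly positive")
        unknown = {e for e in self.elements if _normalize_element(e) not in ATOMIC_MASSES}
        if unknown:
            raise FormatError(f"unrecognized element symbol(s): {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return len(self.labels)


@dataclasses.dataclass
class Ensemble:
    """Shared atom metadata plus an ordered stack of coordinate frames."""

    labels: list[str]
    elements: list[str]
    masses: np.ndarray  # (n,)
    coords: np.ndarray  # (n_frames, n, 3)
    provenance: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise FormatError("ensemble needs at least one (n_atoms, 3) frame")
        if self.coords.shape[1] != len(self.labels) or self.coords.shape[2] != 3:
            raise FormatError("frame shape does not match atom metadata")
        if not self.provenance:
            self.provenance = [f"frame {i}" for i in range(self.n_frames)]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return Structure(self.labels, self.elements, self.masses, self.coords[i])

    @classmethod
    def from_frames(cls, frames: Sequence[Structure], provenance: list[str] | None = None) -> "Ensemble":
        first = frames[0]
        for k, f in enumerate(frames):
            if f.n_atoms != first.n_atoms:
                raise FormatError(
                    f"frame {k} has {f.n_atoms} atoms, expected {first.n_atoms}"
                )
        coords = np.stack([f.coords for f in frames])
        return cls(first.labels, first.elements, first.masses, coords,
                   provenance or [])


@dataclasses.dataclass
class ChargeSet:
    """Per-atom partial charges (e) and radii (Angstrom)."""

    charges: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.charges.shape != self.radii.shape or self.charges.ndim != 1:
            raise FormatError("charges and radii must be equal-length 1-D arrays")
        if np.any(self.radii <= 0):
            raise FormatError("radii must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return self.charges.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def check_alignment(self, n_atoms: int) -> None:
        if self.n_atoms != n_atoms:
            raise AlignmentError(
                f"charge set has {self.n_atoms} entries for a {n_atoms}-atom structure"
            )


def _normalize_element(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        return s
    return s.capitalize() if len(s) > 1 else s.upper()


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Used when the element column is blank: take the alphabetic prefix of
    the name (digits stripped), prefer a recognized two-letter element,
    otherwise fall back to the first letter.
    """
    m = re.search(r"[A-Za-z]+", atom_name)
    if not m:
        raise FormatError(f"cannot infer element from atom name {atom_name!r}")
    alpha = m.group(0)
    if len(alpha) >= 2:
        two = _normalize_element(alpha[:2])
        if two in TWO_LETTER_ELEMENTS:
            return two
    one = alpha[0].upper()
    if one not in ATOMIC_MASSES:
        raise FormatError(f"cannot infer element from atom name {atom_name!r}")
    return one


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz_ensemble(path: str | Path) -> Ensemble:
    """Read a (multi-frame) XYZ file.

    Each frame is an atom-count line, a comment line, then that many
    ``element x y z`` lines. All frames must share atom count and order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] = []
    provenance: list[str] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"{path.name}: expected atom count at line {i + 1}, got {lines[i]!r}"
            ) from exc
        block = lines[i + 2: i + 2 + natoms]
        if len(block) < natoms:
            raise FormatError(
                f"{path.name}: frame {frame_no} declares {natoms} atoms but only "
                f"{len(block)} atom lines follow"
            )
        frame_elems: list[str] = []
        xyz = np.empty((natoms, 3))
        for a, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path.name}: line {i + 3 + a}: expected 'element x y z', got {line!r}"
                )
            frame_elems.append(_normalize_element(parts[0]))
            try:
                xyz[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: line {i + 3 + a}: non-numeric coordinate in {line!r}"
                ) from exc
        if frames and natoms != frames[0].shape[0]:
            raise FormatError(
                f"{path.name}: frame {frame_no} has {natoms} atoms, "
                f"expected {frames[0].shape[0]}"
            )
        if not frames:
            elements = frame_elems
        frames.append(xyz)
        provenance.append(f"{path.name} frame {frame_no}")
        frame_no += 1
        i += 2 + natoms
    if not frames:
        raise FormatError(f"{path.name}: no frames found")
    labels = [f"{e}{k + 1}" for k, e in enumerate(elements)]
    masses = np.array([element_mass(e) for e in elements])
    return Ensemble(labels, elements, masses, np.stack(frames), provenance)


def write_xyz_ensemble(ensemble: Ensemble, path: str | Path,
                       comment: str = "") -> None:
    path = Path(path)
    out: list[str] = []
    for f in range(ensemble.n_frames):
        out.append(str(ensemble.n_atoms))
        out.append(comment or ensemble.provenance[f])
        for e, (x, y, z) in zip(ensemble.elements, ensemble.coords[f]):
            out.append(f"{e:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    path.write_text("\n".join(out) + "\n")


def write_xyz(structure: Structure, path: str | Path, comment: str = "") -> None:
    ens = Ensemble(structure.labels, structure.elements, structure.masses,
                   structure.coords[None])
    write_xyz_ensemble(ens, path, comment=comment)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int, name: str):
    atom_name = line[12:16].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise FormatError(f"{name}: line {lineno}: non-numeric coordinate") from exc
    element = line[76:78].strip() if len(line) >= 77 else ""
    if element:
        element = _normalize_element(element)
    else:
        element = infer_element(atom_name)
    return atom_name, element, (x, y, z)


def read_pdb_ensemble(path: str | Path) -> Ensemble:
    """Read ATOM/HETATM records, one frame per MODEL block.

    A file without MODEL records is a single implicit frame. Blank
    element columns fall back to inference from the atom name.
    """
    path = Path(path)
    frames: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    saw_model = False
    model_ids: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = []
            model_ids.append(line[6:].strip() or str(len(model_ids) + 1))
        elif rec == "ENDMDL":
            in_model = False
            frames.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_pdb_atom(line, lineno, path.name))
    if current:
        # unclosed MODEL block, or a file with no MODEL records at all
        frames.append(current)
        if not saw_model:
            model_ids.append("1")
    frames = [f for f in frames if f]
    if not frames:
        raise FormatError(f"{path.name}: no ATOM/HETATM records found")
    n0 = len(frames[0])
    for k, f in enumerate(frames):
        if len(f) != n0:
            raise FormatError(
                f"{path.name}: MODEL block {k} has {len(f)} atoms, expected {n0}"
            )
    labels = [a[0] for a in frames[0]]
    elements = [a[1] for a in frames[0]]
    masses = np.array([element_mass(e) for e in elements])
    coords = np.array([[a[2] for a in f] for f in frames])
    provenance = [f"{path.name} model {model_ids[k] if k < len(model_ids) else k + 1}"
                  for k in range(len(frames))]
    return Ensemble(labels, elements, masses, coords, provenance)


def write_pdb(structure: Structure, path: str | Path,
              bfactors: np.ndarray | None = None,
              occupancies: np.ndarray | None = None) -> None:
    """Write a single-model PDB; ``bfactors`` fills the B-factor column."""
    path = Path(path)
    b = np.zeros(structure.n_atoms) if bfactors is None else np.asarray(bfactors)
    occ = np.ones(structure.n_atoms) if occupancies is None else np.asarray(occupancies)
    lines = []
    for i in range(structure.n_atoms):
        name = structure.labels[i][:4]
        x, y, z = structure.coords[i]
        lines.append(
            f"HETATM{i + 1:5d} {name:<4s} MOL A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ[i]:6.2f}{b[i]:6.2f}          "
            f"{structure.elements[i]:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    path = Path(path)
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL {f + 1:8d}")
        for i in range(ensemble.n_atoms):
            name = ensemble.labels[i][:4]
            x, y, z = ensemble.coords[f, i]
            lines.append(
                f"HETATM{i + 1:5d} {name:<4s} MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{ensemble.elements[i]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def read_charges(path: str | Path, n_atoms: int | None = None) -> ChargeSet:
    """Read per-atom charges/radii from PQR or a 2-/3-column table.

    PQR: whitespace-separated ATOM/HETATM records with charge then radius
    after the coordinates. Tabular: ``index charge [radius]`` per line,
    1-based indices; missing radii default to 1.5 A.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    charges: list[float] = []
    radii: list[float] = []
    is_pqr = any(line[:6].strip() in ("ATOM", "HETATM") for line in text)
    if is_pqr:
        for lineno, line in enumerate(text, start=1):
            if line[:6].strip() not in ("ATOM", "HETATM"):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise FormatError(f"{path.name}: line {lineno}: short PQR record")
            try:
                charges.append(float(parts[-2]))
                radii.append(float(parts[-1]))
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: line {lineno}: non-numeric charge/radius"
                ) from exc
    else:
        entries: dict[int, tuple[float, float]] = {}
        for lineno, line in enumerate(text, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                idx = int(parts[0])
                q = float(parts[1])
                r = float(parts[2]) if len(parts) > 2 else 1.5
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path.name}: line {lineno}: expected 'index charge [radius]'"
                ) from exc
            entries[idx - 1] = (q, r)
        if entries:
            order = sorted(entries)
            if order != list(range(len(order))):
                raise FormatError(f"{path.name}: atom indices are not contiguous from 1")
            charges = [entries[i][0] for i in order]
            radii = [entries[i][1] for i in order]
    if not charges:
        raise FormatError(f"{path.name}: no charge entries found")
    cs = ChargeSet(np.array(charges), np.array(radii))
    if n_atoms is not None:
        cs.check_alignment(n_atoms)
    return cs


def write_pqr(structure: Structure, charges: ChargeSet, path: str | Path) -> None:
    charges.check_alignment(structure.n_atoms)
    path = Path(path)
    lines = []
    for i in range(structure.n_atoms):
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {structure.labels[i][:4]:<4s} MOL     1    "
            f"{x:8.3f} {y:8.3f} {z:8.3f} {charges.charges[i]:8.4f} {charges.radii[i]:7.4f}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def read_energy_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited per-frame energy table (comma or tab, header row).

    ``kinetic`` and ``potential`` columns are mandatory; bonded-term
    columns are optional and absent columns stay absent (never zero).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ENERGY_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory energy column(s): {', '.join(missing)}"
        )
    return df


def write_energy_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
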