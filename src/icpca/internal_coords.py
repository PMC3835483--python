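"""Molecular graph and internal-coordinate measurement.

The covalent graph is the single source of truth for which internal
coordinates exist: bond lengths are graph edges, bond angles are 2-paths
around a central atom, and proper dihedrals are 4-paths a-b-c-d around a
central bond b-c. Geometry is then measured frame-by-frame directly from
Cartesian coordinates. Improper torsions are never enumerated.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .constants import element_mass
from .errors import FormatError, InputError
from .io import Ensemble

__all__ = [
    "MolecularGraph",
    "FeatureSet",
    "FeatureMatrix",
    "enumerate_bonds",
    "enumerate_angles",
    "enumerate_dihedrals",
    "measure",
]

Kind = Literal["bond", "angle", "dihedral"]

#: degrees of arc below which the defining planes of a torsion are
#: considered degenerate (three collinear atoms)
_DEGENERATE_SIN = 1e-9


class MolecularGraph:
    """Atoms (element, mass, display label) plus covalent bonds.

    Labels default to element + 1-based index (carbon-numbering style);
    bond input is validated against self-bonds and duplicates.
    """

    def __init__(self, elements: Sequence[str],
                 bonds: Iterable[tuple[int, int]],
                 labels: Sequence[str] | None = None,
                 masses: Sequence[float] | None = None):
        self.elements = [str(e) for e in elements]
        n = len(self.elements)
        self.labels = list(labels) if labels is not None else [
            f"{e}{i + 1}" for i, e in enumerate(self.elements)
        ]
        if len(self.labels) != n:
            raise InputError("label count does not match atom count")
        if masses is None:
            self.masses = np.array([element_mass(e) for e in self.elements])
        else:
            self.masses = np.asarray(masses, dtype=float)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        seen: set[tuple[int, int]] = set()
        for a, b in bonds:
            a, b = int(a), int(b)
            if a == b:
                raise InputError(f"self-bond on atom {a + 1}")
            if not (0 <= a < n and 0 <= b < n):
                raise InputError(f"bond ({a + 1}, {b + 1}) out of range")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise InputError(f"duplicate bond ({key[0] + 1}, {key[1] + 1})")
            seen.add(key)
            g.add_edge(*key)
        self.graph = g

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_cycles(self) -> int:
        """Number of independent cycles (circuit rank)."""
        return (self.n_bonds - self.n_atoms
                + nx.number_connected_components(self.graph))

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.graph.neighbors(i))

    def bonded_hydrogens(self, i: int) -> list[int]:
        return [j for j in self.graph.neighbors(i) if self.elements[j] == "H"]

    @classmethod
    def from_bond_list_file(cls, path: str | Path,
                            elements: Sequence[str],
                            labels: Sequence[str] | None = None) -> "MolecularGraph":
        """Read bonds from a text file with two 1-based indices per line."""
        bonds = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected two atom indices")
            try:
                bonds.append((int(parts[0]) - 1, int(parts[1]) - 1))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer atom index") from exc
        return cls(elements, bonds, labels=labels)

    def write_bond_list(self, path: str | Path) -> None:
        lines = [f"{a + 1} {b + 1}" for a, b in
                 sorted((min(e), max(e)) for e in self.graph.edges)]
        Path(path).write_text("\n".join(lines) + "\n")


def _canonical(tup: tuple[int, ...]) -> tuple[int, ...]:
    return tup if tup[0] < tup[-1] else tup[::-1]


@dataclasses.dataclass
class FeatureSet:
    """An ordered, canonicalized list of internal coordinates of one kind."""

    kind: Kind
    tuples: list[tuple[int, ...]]
    graph: MolecularGraph | None = None

    def __post_init__(self) -> None:
        width = {"bond": 2, "angle": 3, "dihedral": 4}[self.kind]
        canon = [_canonical(tuple(int(i) for i in t)) for t in self.tuples]
        for t in canon:
            if len(t) != width:
                raise InputError(f"{self.kind} feature {t} has wrong arity")
        if len(set(canon)) != len(canon):
            raise InputError("duplicate features after canonicalization")
        self.tuples = canon

    def __len__(self) -> int:
        return len(self.tuples)

    def __iter__(self):
        return iter(self.tuples)

    def labels(self) -> list[str]:
        """Human-readable feature identities using graph display labels."""
        if self.graph is None:
            return ["-".join(str(i + 1) for i in t) for t in self.tuples]
        return ["-".join(self.graph.labels[i] for i in t) for t in self.tuples]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["kind\tfeature\tatoms_1based"]
        for t, lab in zip(self.tuples, self.labels()):
            lines.append(f"{self.kind}\t{lab}\t" + ",".join(str(i + 1) for i in t))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass
class FeatureMatrix:
    """frames x features values for one feature kind.

    Units: Angstrom for bonds, degrees for angles ([0, 180]) and
    dihedrals ((-180, 180], IUPAC sign convention). ``mask`` marks cells
    whose torsion was degenerate (three collinear defining atoms).
    """

    values: np.ndarray
    features: FeatureSet
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.features):
            raise InputError("value matrix shape does not match feature set")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)

    @property
    def kind(self) -> Kind:
        return self.features.kind

    @property
    def units(self) -> str:
        return "angstrom" if self.kind == "bond" else "degrees"

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(self.features.labels())
        rows = ["\t".join(f"{v:.6f}" for v in row) for row in self.values]
        Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")


def enumerate_bonds(graph: MolecularGraph) -> FeatureSet:
    """Every bonded pair exactly once, canonical (low, high) order."""
    edges = sorted(_canonical(tuple(e)) for e in graph.graph.edges)
    return FeatureSet("bond", edges, graph)


def enumerate_angles(graph: MolecularGraph) -> FeatureSet:
    """One angle per unordered neighbor pair around each central atom."""
    angles = []
    for b in range(graph.n_atoms):
        for a, c in combinations(graph.neighbors(b), 2):
            angles.append(_canonical((a, b, c)))
    return FeatureSet("angle", sorted(angles), graph)


def enumerate_dihedrals(graph: MolecularGraph) -> FeatureSet:
    """All proper torsions a-b-c-d around each bond b-c.

    For every edge (b, c), every a in N(b)\\{c} and d in N(c)\\{b} with
    a != d defines one torsion; canonicalization keeps each 4-path once.
    """
    dihedrals = set()
    for b, c in graph.graph.edges:
        for a in graph.neighbors(b):
            if a == c:
                continue
            for d in graph.neighbors(c):
                if d == b or d == a:
                    continue
                dihedrals.add(_canonical((a, b, c, d)))
    return FeatureSet("dihedral", sorted(dihedrals), graph)


def enumerate_features(graph: MolecularGraph, kind: Kind) -> FeatureSet:
    return {"bond": enumerate_bonds,
            "angle": enumerate_angles,
            "dihedral": enumerate_dihedrals}[kind](graph)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _bond_lengths(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    d = coords[:, idx[:, 0]] - coords[:, idx[:, 1]]
    return np.linalg.norm(d, axis=-1)


def _angles_deg(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    u = coords[:, idx[:, 0]] - coords[:, idx[:, 1]]
    v = coords[:, idx[:, 2]] - coords[:, idx[:, 1]]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cos = np.einsum("fij,fij->fi", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def _dihedrals_deg(coords: np.ndarray, idx: np.ndarray):
    """Signed torsions, IUPAC convention (cis = 0, right-hand rule about b-c).

    Returns (values in (-180, 180], degenerate mask).
    """
    b1 = coords[:, idx[:, 1]] - coords[:, idx[:, 0]]
    b2 = coords[:, idx[:, 2]] - coords[:, idx[:, 1]]
    b3 = coords[:, idx[:, 3]] - coords[:, idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.einsum("fij,fij->fi", n1, n2)
    y = np.einsum("fij,fij->fi", np.cross(n1, n2), b2 / b2n[..., None])
    deg = np.degrees(np.arctan2(y, x))
    # map the -180 branch point onto +180 so the range is (-180, 180]
    deg = np.where(deg <= -180.0 + 1e-12, deg + 360.0, deg)
    degenerate = (np.linalg.norm(n1, axis=-1) < _DEGENERATE_SIN) | (
        np.linalg.norm(n2, axis=-1) < _DEGENERATE_SIN)
    return deg, degenerate


def measure(ensemble: Ensemble, features: FeatureSet) -> FeatureMatrix:
    """Measure one kind of internal coordinate for every frame.

    Degenerate torsions (collinear defining atoms) are masked per cell,
    never raised, so one pathological frame cannot abort an analysis.
    """
    if not features.tuples:
        raise InputError("empty feature set")
    idx = np.array(features.tuples, dtype=int)
    if idx.max() >= ensemble.n_atoms:
        raise InputError("feature indices exceed ensemble atom count")
    coords = ensemble.coords
    if features.kind == "bond":
        vals = _bond_lengths(coords, idx)
        mask = None
    elif features.kind == "angle":
        vals = _angles_deg(coords, idx)
        mask = None
    else:
        vals, mask = _dihedrals_deg(coords, idx)
        vals = np.where(mask, np.nan, vals)
    return FeatureMatrix(vals, features, mask)
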