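"""Synthetic inputs for every pipeline stage.

No conformational ensembles are distributed with the package, so tests
and examples generate their own: a built-in all-atom sterol graph
(3-beta-hydroxy cholest-5-ene, standard carbon numbering), feature
matrices with a designated high-variance ("hot") subset, unbranched
chain ensembles rebuilt from internal coordinates frame by frame, toy
charge sets, and per-frame energy tables. Every generator is a pure
function of its arguments plus an explicit seed.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constants import vdw_radius
from .errors import InputError
from .internal_coords import FeatureMatrix, FeatureSet, Kind, MolecularGraph
from .io import ChargeSet, Ensemble

__all__ = [
    "SyntheticSpec",
    "cholesterol_fixture",
    "generate_matrix",
    "generate_chain_ensemble",
    "generate_charges",
    "generate_energy_table",
]


# ---------------------------------------------------------------------------
# cholesterol fixture
# ---------------------------------------------------------------------------

# heavy-atom skeleton of cholest-5-en-3beta-ol in standard sterol
# numbering: rings A (C1-C2-C3-C4-C5-C10), B (C5-C6-C7-C8-C9-C10),
# C (C8-C9-C11-C12-C13-C14), D (C13-C14-C15-C16-C17); angular methyls
# C18 (on C13) and C19 (on C10); iso-octyl side chain C20-C27 on C17;
# 3beta-hydroxyl on C3. The C5=C6 double bond exists only as
# connectivity (C5 and C6 simply carry fewer hydrogens).
_CC_BONDS = [
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 10), (10, 1),          # ring A
    (5, 6), (6, 7), (7, 8), (8, 9), (9, 10),                   # ring B
    (8, 14), (14, 13), (13, 12), (12, 11), (11, 9),            # ring C
    (14, 15), (15, 16), (16, 17), (17, 13),                    # ring D
    (13, 18), (10, 19),                                        # methyls
    (17, 20), (20, 21), (20, 22), (22, 23), (23, 24),
    (24, 25), (25, 26), (25, 27),                              # side chain
]

# hydrogens per carbon (sums to 45; the hydroxyl H is the 46th)
_H_COUNT = {
    1: 2, 2: 2, 3: 1, 4: 2, 5: 0, 6: 1, 7: 2, 8: 1, 9: 1, 10: 0,
    11: 2, 12: 2, 13: 0, 14: 1, 15: 2, 16: 2, 17: 1, 18: 3, 19: 3,
    20: 1, 21: 3, 22: 2, 23: 2, 24: 2, 25: 1, 26: 3, 27: 3,
}


def cholesterol_fixture() -> MolecularGraph:
    """All-atom 3-beta-hydroxy cholest-5-ene graph (C27H46O, 74 atoms).

    Carbons are labelled ``C1`` ... ``C27`` following the standard
    sterol numbering, the hydroxyl oxygen ``O``, its hydrogen ``HO``,
    and carbon-bound hydrogens ``H<carbon><letter>`` (e.g. ``H18B``).
    """
    elements = ["C"] * 27 + ["O"]
    labels = [f"C{i}" for i in range(1, 28)] + ["O"]
    bonds = [(a - 1, b - 1) for a, b in _CC_BONDS]
    o_index = 27
    bonds.append((3 - 1, o_index))            # C3-O
    # hydroxyl hydrogen
    elements.append("H")
    labels.append("HO")
    bonds.append((o_index, len(elements) - 1))
    # carbon-bound hydrogens
    for carbon in range(1, 28):
        for k in range(_H_COUNT[carbon]):
            elements.append("H")
            labels.append(f"H{carbon}{chr(ord('A') + k)}")
            bonds.append((carbon - 1, len(elements) - 1))
    return MolecularGraph(elements, bonds, labels=labels)


# ---------------------------------------------------------------------------
# feature matrices with known variance structure
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticSpec:
    """Recipe for a feature matrix with a designated hot subset.

    Defaults mirror the study conditions the pipeline is meant for:
    250 frames over 77 features (one per bond of the sterol fixture),
    with the hot features fluctuating at 10x the baseline standard
    deviation (a 100x variance ratio).
    """

    n_frames: int = 250
    n_features: int = 77
    hot: tuple[int, ...] = (3, 10, 25)
    sigma_hot: float = 10.0
    sigma_cold: float = 1.0
    kind: Kind = "bond"
    baseline: float | None = None
    hot_near_branch_cut: bool = False
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.n_features < 1:
            raise InputError("need at least 2 frames and 1 feature")
        if self.sigma_hot <= 0 or self.sigma_cold <= 0:
            raise InputError("standard deviations must be positive")
        if any(not 0 <= h < self.n_features for h in self.hot):
            raise InputError("hot feature index out of range")
        if not 0.0 <= self.correlation < 1.0:
            raise InputError("correlation must be in [0, 1)")


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    out = np.mod(a + 180.0, 360.0) - 180.0
    return np.where(out <= -180.0 + 1e-12, out + 360.0, out)


def generate_matrix(spec: SyntheticSpec) -> FeatureMatrix:
    """Gaussian feature matrix about a fixed baseline, seeded.

    Hot features use ``sigma_hot``, the rest ``sigma_cold``. Dihedral
    matrices are wrapped into (-180, 180]; with ``hot_near_branch_cut``
    the hot baselines sit at +/-180 degrees to exercise the circular
    re-wrapping of the PCA preprocessing.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.baseline is None:
        base_value = {"bond": 1.53, "angle": 111.0, "dihedral": 60.0}[spec.kind]
    else:
        base_value = spec.baseline
    baseline = np.full(spec.n_features, base_value)
    sigma = np.full(spec.n_features, spec.sigma_cold)
    for h in spec.hot:
        sigma[h] = spec.sigma_hot
        if spec.kind == "dihedral" and spec.hot_near_branch_cut:
            baseline[h] = 180.0
    z = rng.standard_normal((spec.n_frames, spec.n_features))
    if spec.correlation > 0.0:
        shared = rng.standard_normal((spec.n_frames, 1))
        z = (np.sqrt(1 - spec.correlation) * z
             + np.sqrt(spec.correlation) * shared)
    values = baseline + sigma * z
    if spec.kind == "dihedral":
        values = _wrap_deg(values)
    width = {"bond": 2, "angle": 3, "dihedral": 4}[spec.kind]
    tuples = [tuple(range(i * width, i * width + width))
              for i in range(spec.n_features)]
    return FeatureMatrix(values, FeatureSet(spec.kind, tuples))


# ---------------------------------------------------------------------------
# chain ensembles rebuilt from internal coordinates
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d from a-b-c plus (c-d bond, b-c-d angle, a-b-c-d torsion).

    Sequential natural-extension placement; the torsion follows the same
    sign convention the measurement code uses (cis = 0, right-hand rule
    about the b-c axis).
    """
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise InputError("collinear a-b-c: torsion reference undefined")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(phi),
                        bond * np.sin(theta) * np.sin(phi)])
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d_local


def chain_from_internal(bonds: np.ndarray, angles: np.ndarray,
                        torsions: np.ndarray) -> np.ndarray:
    """Cartesian coordinates of an unbranched chain from its internal
    coordinates (n-1 bonds, n-2 angles, n-3 torsions)."""
    n = bonds.shape[0] + 1
    coords = np.zeros((n, 3))
    coords[1] = [bonds[0], 0.0, 0.0]
    if n > 2:
        theta = np.radians(angles[0])
        coords[2] = coords[1] + bonds[1] * np.array(
            [-np.cos(theta), np.sin(theta), 0.0])
    for i in range(3, n):
        coords[i] = _place_atom(coords[i - 3], coords[i - 2], coords[i - 1],
                                bonds[i - 1], angles[i - 2], torsions[i - 3])
    return coords


def generate_chain_ensemble(n_atoms: int = 6, n_frames: int = 250,
                            hot_torsion: int = 0, amplitude: float = 60.0,
                            jitter: float = 2.0, seed: int = 0,
                            bond_length: float = 1.53,
                            bond_angle: float = 111.0,
                            base_torsion: float = 180.0,
                            ) -> tuple[Ensemble, MolecularGraph, np.ndarray]:
    """Unbranched heavy-atom chain with one designated oscillating torsion.

    Bond lengths (1.53 A) and angles (111 deg) are held fixed; the hot
    torsion swings sinusoidally over the frames with the given amplitude
    while every torsion additionally receives Gaussian jitter. Cartesian
    frames are rebuilt from the internal coordinates by sequential
    placement. Returns (ensemble, graph, torsion matrix actually used),
    the last with one column per torsion in chain order.
    """
    if n_atoms < 4:
        raise InputError("need at least 4 atoms for a torsion")
    n_torsions = n_atoms - 3
    if not 0 <= hot_torsion < n_torsions:
        raise InputError("hot torsion index out of range")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    torsions = np.full((n_frames, n_torsions), base_torsion)
    torsions[:, hot_torsion] += amplitude * np.sin(2.0 * np.pi * t / max(n_frames, 1))
    if jitter > 0:
        torsions += rng.normal(0.0, jitter, size=torsions.shape)
    torsions = _wrap_deg(torsions)
    bonds = np.full(n_atoms - 1, bond_length)
    angles = np.full(n_atoms - 2, bond_angle)
    frames = np.stack([chain_from_internal(bonds, angles, torsions[f])
                       for f in range(n_frames)])
    elements = ["C"] * n_atoms
    graph = MolecularGraph(elements, [(i, i + 1) for i in range(n_atoms - 1)])
    ens = Ensemble(graph.labels, elements, graph.masses, frames,
                   [f"chain frame {f}" for f in range(n_frames)])
    return ens, graph, torsions


# ---------------------------------------------------------------------------
# charges and energies
# ---------------------------------------------------------------------------

ChargePattern = Literal["neutral", "dipole", "fixture-like"]


def generate_charges(graph: MolecularGraph,
                     pattern: ChargePattern = "neutral",
                     magnitude: float = 0.4,
                     dipole_atoms: tuple[int, int] | None = None,
                     seed: int = 0) -> ChargeSet:
    """Toy charge sets: all-zero, a +/-q pair, or a hydroxyl-polarized
    sterol pattern (negative O, positive HO and C3, everything else 0;
    net charge zero in every pattern). Radii come from the vdW table.
    """
    n = graph.n_atoms
    charges = np.zeros(n)
    if pattern == "dipole":
        if dipole_atoms is None:
            dipole_atoms = (0, n - 1)
        a, b = dipole_atoms
        charges[a] = magnitude
        charges[b] = -magnitude
    elif pattern == "fixture-like":
        idx = {lab: i for i, lab in enumerate(graph.labels)}
        for needed in ("O", "HO", "C3"):
            if needed not in idx:
                raise InputError("fixture-like pattern needs O/HO/C3 labels")
        charges[idx["O"]] = -1.5 * magnitude
        charges[idx["HO"]] = magnitude
        charges[idx["C3"]] = 0.5 * magnitude
    elif pattern != "neutral":
        raise InputError(f"unknown charge pattern {pattern!r}")
    radii = np.array([vdw_radius(e) for e in graph.elements])
    return ChargeSet(charges, radii)


def generate_energy_table(n_frames: int = 250,
                          means: dict[str, float] | None = None,
                          noise: float = 1.0,
                          seed: int = 0) -> pd.DataFrame:
    """Gaussian per-frame energy series about stated column means."""
    if noise < 0:
        raise InputError("noise scale must be nonnegative")
    if means is None:
        means = {"kinetic": 100.0, "potential": 100.0,
                 "bond": 10.0, "angle": 20.0, "dihedral": 20.0}
    rng = np.random.default_rng(seed)
    data = {col: mu + noise * rng.standard_normal(n_frames)
            for col, mu in means.items()}
    return pd.DataFrame(data)
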