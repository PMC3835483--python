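"""Membrane-internal electrostatic potential on a molecular dot surface.

A deliberately transparent two-dielectric screened-Coulomb model: each
atom is tagged either ``polar_head`` (the membrane head-group domain,
methanol-like dielectric) or ``core`` (hydrophobic interior,
cyclohexane-like), and the potential at a surface point p is

    phi(p) = k_C / eps(region of p) * sum_i q_i / |p - r_i|

expressed in kT per elementary charge at the configured temperature.
This is not a Poisson or boundary-element solver: magnitudes are
approximate, but the sign and location of positive/negative surface
patches — the qualitative membrane-facing picture — are preserved.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np

from .constants import (BOLTZMANN_EV, COULOMB_EV_ANGSTROM,
                        DEFAULT_TEMPERATURE_K, EPSILON_CYCLOHEXANE,
                        EPSILON_METHANOL, vdw_radius)
from .errors import InputError, NumericalError
from .internal_coords import MolecularGraph
from .io import ChargeSet, Structure, write_pdb

__all__ = [
    "RegionAssignment",
    "SurfacePoints",
    "SurfaceESP",
    "assign_regions",
    "sample_surface",
    "esp_at_points",
    "compute_surface_esp",
]

POLAR = "polar_head"
CORE = "core"

#: tolerance for the buried-point test and the coincident-charge mask
_BURIAL_TOL = 1e-9


@dataclasses.dataclass
class RegionAssignment:
    """Per-atom membrane-domain tag plus the dielectric of each region."""

    tags: list[str]                      # POLAR or CORE per atom
    dielectrics: dict[str, float]

    def __post_init__(self) -> None:
        bad = {t for t in self.tags} - {POLAR, CORE}
        if bad:
            raise InputError(f"unknown region tag(s): {bad}")
        for region, eps in self.dielectrics.items():
            if eps < 1.0:
                raise InputError(f"dielectric of {region} must be >= 1")

    def epsilon(self) -> np.ndarray:
        return np.array([self.dielectrics[t] for t in self.tags])


def assign_regions(graph: MolecularGraph, polar_atoms: Sequence[int],
                   include_bonded_hydrogens: bool = True,
                   eps_polar: float = EPSILON_METHANOL,
                   eps_core: float = EPSILON_CYCLOHEXANE) -> RegionAssignment:
    """Tag the listed atoms (plus, by default, their bonded hydrogens)
    as the polar head-group domain; everything else is hydrophobic core.
    """
    polar = set()
    for i in polar_atoms:
        if not 0 <= i < graph.n_atoms:
            raise InputError(f"polar atom index {i} out of range")
        polar.add(int(i))
        if include_bonded_hydrogens:
            polar.update(graph.bonded_hydrogens(int(i)))
    if not polar:
        warnings.warn("empty polar region: whole molecule tagged core",
                      stacklevel=2)
    tags = [POLAR if i in polar else CORE for i in range(graph.n_atoms)]
    return RegionAssignment(tags, {POLAR: eps_polar, CORE: eps_core})


def default_polar_atoms(graph: MolecularGraph) -> list[int]:
    """Head-group heavy atoms for a sterol fixture: O and ring carbons
    C2, C3, C4 (their hydrogens are picked up by :func:`assign_regions`).
    """
    wanted = {"O", "C2", "C3", "C4"}
    out = [i for i, lab in enumerate(graph.labels) if lab in wanted]
    if len(out) != len(wanted):
        raise InputError("graph labels do not expose O/C2/C3/C4")
    return out


@dataclasses.dataclass
class SurfacePoints:
    """Dot-surface samples, each tied to the atom sphere it lies on."""

    points: np.ndarray        # (m, 3) Angstrom
    parent_atom: np.ndarray   # (m,) int
    scaled_radii: np.ndarray  # per atom, Angstrom

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere sampling (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sample_surface(structure: Structure, radii: Sequence[float] | None = None,
                   scale: float = 1.1, density: float = 5.0) -> SurfacePoints:
    """Sample the solvent-excluded dot surface of scaled vdW spheres.

    Each atom sphere (radius x ``scale``) is covered quasi-uniformly at
    ``density`` points per square Angstrom; points strictly inside any
    other atom's scaled sphere are removed.
    """
    if scale < 1.0:
        raise InputError("radius scale must be >= 1")
    if density <= 0:
        raise InputError("density must be positive")
    if radii is None:
        radii = [vdw_radius(e) for e in structure.elements]
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (structure.n_atoms,) or np.any(radii <= 0):
        raise InputError("need one positive radius per atom")
    scaled = radii * scale
    pts, parents = [], []
    for i in range(structure.n_atoms):
        r = scaled[i]
        n = max(int(np.ceil(density * 4.0 * np.pi * r * r)), 4)
        sphere = structure.coords[i] + r * _fibonacci_sphere(n)
        keep = np.ones(n, dtype=bool)
        for j in range(structure.n_atoms):
            if j == i:
                continue
            d = np.linalg.norm(sphere - structure.coords[j], axis=1)
            keep &= d >= scaled[j] - _BURIAL_TOL
        if keep.any():
            pts.append(sphere[keep])
            parents.append(np.full(int(keep.sum()), i))
    if not pts:
        raise NumericalError("no surface points survive occlusion: degenerate geometry")
    return SurfacePoints(np.concatenate(pts), np.concatenate(parents), scaled)


@dataclasses.dataclass
class SurfaceESP:
    """Surface samples with region tags and potentials in kT/e."""

    points: np.ndarray
    parent_atom: np.ndarray
    region: list[str]
    phi: np.ndarray            # raw, kT/e
    phi_clamped: np.ndarray    # clipped to +/- clamp for display
    clamp: float
    temperature: float
    masked: np.ndarray         # True where a point coincides with a charge

    def to_tsv(self, path: str | Path) -> None:
        lines = ["x\ty\tz\tparent_atom_1based\tregion\tphi_kT_per_e\tphi_clamped"]
        for k in range(self.points.shape[0]):
            x, y, z = self.points[k]
            lines.append(
                f"{x:.4f}\t{y:.4f}\t{z:.4f}\t{self.parent_atom[k] + 1}\t"
                f"{self.region[k]}\t{self.phi[k]:.6g}\t{self.phi_clamped[k]:.6g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_pdb(self, path: str | Path) -> None:
        """Point cloud as a PDB dialect with phi (clamped) in B-factors."""
        n = self.points.shape[0]
        s = Structure(labels=[f"S{k % 9999 + 1}" for k in range(n)],
                      elements=["He"] * n,
                      masses=np.full(n, 4.0026),
                      coords=self.points)
        write_pdb(s, path, bfactors=self.phi_clamped)


def esp_at_points(surface: SurfacePoints, structure: Structure,
                  charges: ChargeSet, regions: RegionAssignment,
                  temperature: float = DEFAULT_TEMPERATURE_K,
                  clamp: float = 5.0) -> SurfaceESP:
    """Screened-Coulomb potential at every surface point, in kT/e.

    The dielectric applied to a point is that of its parent atom's
    region (sharp two-domain boundary). Points coincident with an atom
    center are masked (phi set to NaN), not raised.
    """
    charges.check_alignment(structure.n_atoms)
    if temperature <= 0:
        raise InputError("temperature must be positive (K)")
    diff = surface.points[:, None, :] - structure.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    masked = (dist < _BURIAL_TOL).any(axis=1)
    with np.errstate(divide="ignore"):
        raw_sum = (charges.charges[None, :] / dist).sum(axis=1)
    eps_atom = regions.epsilon()
    eps_point = eps_atom[surface.parent_atom]
    kT = BOLTZMANN_EV * temperature
    phi = COULOMB_EV_ANGSTROM / eps_point * raw_sum / kT
    phi[masked] = np.nan
    region = [regions.tags[i] for i in surface.parent_atom]
    return SurfaceESP(surface.points, surface.parent_atom, region,
                      phi, np.clip(phi, -clamp, clamp), clamp,
                      temperature, masked)


def compute_surface_esp(structure: Structure, graph: MolecularGraph,
                        charges: ChargeSet, polar_atoms: Sequence[int],
                        eps_polar: float = EPSILON_METHANOL,
                        eps_core: float = EPSILON_CYCLOHEXANE,
                        scale: float = 1.1, density: float = 5.0,
                        temperature: float = DEFAULT_TEMPERATURE_K,
                        clamp: float = 5.0) -> SurfaceESP:
    """One-shot: assign regions, sample the surface, evaluate potentials."""
    regions = assign_regions(graph, polar_atoms,
                             eps_polar=eps_polar, eps_core=eps_core)
    surface = sample_surface(structure, radii=list(charges.radii)
                             if charges.radii.size == structure.n_atoms else None,
                             scale=scale, density=density)
    return esp_at_points(surface, structure, charges, regions,
                         temperature=temperature, clamp=clamp)
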