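"""Physical constants and per-element lookup tables.

All geometry is in Angstrom, charges in elementary charge units (e),
masses in amu, energies in eV where dimensional, potentials in kT/e.
"""

from __future__ import annotations

# Coulomb constant k_C = 1/(4 pi eps0) in eV * Angstrom / e^2
COULOMB_EV_ANGSTROM = 14.3996

# Boltzmann constant in eV / K
BOLTZMANN_EV = 8.617333262e-5

DEFAULT_TEMPERATURE_K = 300.0

#: standard atomic masses (amu), common biomolecular + organic elements
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Mn": 54.938, "Fe": 55.845, "Co": 58.933,
    "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Se": 78.971,
    "Br": 79.904, "I": 126.904,
}

#: Bondi-style van der Waals radii (Angstrom); fallback 1.7 for others
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Na": 2.27, "K": 2.75, "Mg": 1.73, "Ca": 2.31, "Zn": 1.39,
}

DEFAULT_VDW_RADIUS = 1.70

#: two-letter element symbols recognized when inferring elements from
#: atom names with a blank element column (legacy PDB snapshots)
TWO_LETTER_ELEMENTS = frozenset(
    e for e in ATOMIC_MASSES if len(e) == 2
)

# handbook relative permittivities of the two membrane-domain model solvents
EPSILON_METHANOL = 32.6
EPSILON_CYCLOHEXANE = 2.02


def element_mass(element: str) -> float:
    """Mass (amu) of ``element``; raises ``KeyError`` for unknown symbols."""
    return ATOMIC_MASSES[element.capitalize() if len(element) > 1 else element.upper()]


def vdw_radius(element: str) -> float:
    sym = element.capitalize() if len(element) > 1 else element.upper()
    return VDW_RADII.get(sym, DEFAULT_VDW_RADIUS)
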