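"""Physical constants and element data used across the package."""

from __future__ import annotations

import gemmi

#: Mott-Bethe prefactor m_e * e^2 / (8 pi eps0 h^2) in inverse angstroms,
#: evaluated from CODATA 2018 values (scipy.constants); frozen here to
#: 6 significant digits so electron form factors are reproducible.
MOTT_BETHE_CONSTANT = 0.0239337  # Å⁻¹

#: Bohr radius in Å, used to convert bohr⁻¹ radial exponents.
BOHR_ANGSTROM = 0.529177

#: Minimum distance (Å) below which two positions are considered overlapping
#: rather than bonded.
OVERLAP_DISTANCE = 0.4

#: Default tolerance (Å) added to the sum of covalent radii when deciding
#: bonding connectivity.
DEFAULT_BOND_TOLERANCE = 0.40

#: Default RMS out-of-plane deviation (Å) below which a centre and its
#: bonded neighbours are called planar.
DEFAULT_PLANARITY_THRESHOLD = 0.10

# Single-bond covalent radii in Å (Cordero et al.-style consensus values for
# the elements that occur in the fixtures plus common hetero elements; the
# full periodic table is not needed for bond perception here and users can
# override the table).
COVALENT_RADII = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "I": 1.39, "Xe": 1.40,
}


def element_symbol(z: int) -> str:
    """Element symbol for atomic number *z*."""
    return gemmi.Element(z).name


def atomic_number(symbol: str) -> int:
    """Atomic number for an element *symbol* (case-insensitive).

    Raises ``KeyError`` for unknown symbols.
    """
    el = gemmi.Element(symbol.capitalize())
    if el.atomic_number == 0 and symbol.upper() not in ("X",):
        raise KeyError(f"unknown element symbol {symbol!r}")
    return el.atomic_number


def covalent_radius(symbol_or_z) -> float:
    """Covalent single-bond radius in Å."""
    sym = symbol_or_z if isinstance(symbol_or_z, str) else element_symbol(symbol_or_z)
    try:
        return COVALENT_RADII[sym]
    except KeyError:
        # fall back to gemmi's embedded radii for exotic elements
        return gemmi.Element(sym).covalent_r
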