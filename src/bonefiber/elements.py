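"""Element data: standard atomic weights and covalent radii.

Weights are CODATA/IUPAC conventional values; covalent radii are consensus
single-bond radii (Cordero et al. style) used by the distance-based bond
perception heuristic.
"""

from __future__ import annotations

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Mn": 54.938, "Fe": 55.845, "Cu": 63.546,
    "Zn": 65.38, "Se": 78.971, "Br": 79.904, "I": 126.904,
}

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71,
    "O": 0.66, "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Cu": 1.32,
    "Zn": 1.22, "Se": 1.20, "Br": 1.20, "I": 1.39,
}


class UnknownElementError(ValueError):
    """Raised when an element symbol cannot be resolved to a mass."""


def normalize_symbol(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        raise UnknownElementError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def mass_of(symbol: str) -> float:
    s = normalize_symbol(symbol)
    try:
        return ATOMIC_MASS[s]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from None


def covalent_radius_of(symbol: str) -> float:
    s = normalize_symbol(symbol)
    try:
        return COVALENT_RADIUS[s]
    except KeyError:
        raise UnknownElementError(f"no covalent radius for element {symbol!r}") from None


def element_from_atom_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Two-letter symbols are recognized only when the full two-character
    prefix matches a known element with the PDB justification convention
    (two-letter elements start in column 13); otherwise the first
    alphabetic character is used.
    """
    stripped = name.strip()
    if not stripped:
        raise UnknownElementError(f"cannot infer element from atom name {name!r}")
    # PDB convention: names of atoms with two-letter elements occupy
    # columns 13-16 flush left (e.g. "CA  " for calcium ion vs " CA " for
    # an alpha-carbon).
    if len(name) >= 2 and name[0] != " ":
        two = normalize_symbol(name[:2].strip())
        if two in ATOMIC_MASS and len(two) == 2:
            return two
    for ch in stripped:
        if ch.isalpha():
            sym = normalize_symbol(ch)
            if sym in ATOMIC_MASS:
                return sym
            break
    raise UnknownElementError(f"cannot infer element from atom name {name!r}")
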