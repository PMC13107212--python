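"""Physical constants and element data used across the package.

Energies are kJ/mol, distances Å, temperatures K, times s, throughout.
"""

from __future__ import annotations

from scipy import constants as _sc

#: Boltzmann constant, J/K (CODATA, exact by SI definition).
K_B = _sc.k
#: Planck constant, J·s (CODATA, exact).
H_PLANCK = _sc.h
#: Molar gas constant, J/(mol·K).
R_GAS = _sc.R
#: Molar gas constant in kJ/(mol·K); energies in this package are kJ/mol.
R_KJ = _sc.R / 1000.0


def rt_kj(temperature: float) -> float:
    """R·T in kJ/mol at the given temperature in K."""
    return R_KJ * temperature


# Single-bond covalent radii in Å (Cordero et al., Dalton Trans. 2008) and
# atomic numbers, for the elements a reaction-path network of an organic or
# organocatalytic system realistically contains.  C uses the sp3 value.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 0.31), "He": (2, 0.28),
    "Li": (3, 1.28), "Be": (4, 0.96), "B": (5, 0.84), "C": (6, 0.76),
    "N": (7, 0.71), "O": (8, 0.66), "F": (9, 0.57), "Ne": (10, 0.58),
    "Na": (11, 1.66), "Mg": (12, 1.41), "Al": (13, 1.21), "Si": (14, 1.11),
    "P": (15, 1.07), "S": (16, 1.05), "Cl": (17, 1.02), "Ar": (18, 1.06),
    "K": (19, 2.03), "Ca": (20, 1.76), "Sc": (21, 1.70), "Ti": (22, 1.60),
    "V": (23, 1.53), "Cr": (24, 1.39), "Mn": (25, 1.39), "Fe": (26, 1.32),
    "Co": (27, 1.26), "Ni": (28, 1.24), "Cu": (29, 1.32), "Zn": (30, 1.22),
    "Ga": (31, 1.22), "Ge": (32, 1.20), "As": (33, 1.19), "Se": (34, 1.20),
    "Br": (35, 1.20), "Kr": (36, 1.16), "I": (53, 1.39),
}


def atomic_number(symbol: str) -> int:
    try:
        return ELEMENTS[symbol][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    """Single-bond covalent radius in Å; raises ValueError for unknown symbols."""
    try:
        return ELEMENTS[symbol][1]
    except KeyError:
        raise ValueError(f"no covalent radius for element {symbol!r}") from None
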