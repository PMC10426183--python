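"""Physical constants and element tables.

Energies are stored internally in hartree; thermochemistry uses SI.
The element tables carry the IUPAC conventional atomic weights (for
average molar mass and elemental-analysis percentages) and the mass of
each element's most abundant isotope (for monoisotopic / "HRMS calcd"
masses). Both tables are versioned so reports can record exactly which
constants produced them.
"""

from __future__ import annotations

from scipy import constants as _sc

# -- energy units ----------------------------------------------------------

HARTREE_TO_EV = 27.211386  # eV per hartree

# -- SI constants (exact since the 2019 redefinition) ----------------------

PLANCK = _sc.h                   # J s
BOLTZMANN = _sc.k                # J / K
SPEED_OF_LIGHT_CM = _sc.c * 100  # cm / s
AVOGADRO = _sc.N_A               # 1 / mol
GAS_CONSTANT = _sc.R             # J / (mol K)
ATM_PA = 101325.0                # standard pressure, Pa

# second radiation constant h c / k_B in cm K; converts cm^-1 to kelvin
C2_CM_K = PLANCK * SPEED_OF_LIGHT_CM / BOLTZMANN

# -- particle masses in Da -------------------------------------------------

ELECTRON_MASS_DA = 0.000548579909
PROTON_MASS_DA = 1.00782503207 - ELECTRON_MASS_DA  # 1H nucleus

# -- element tables --------------------------------------------------------

MASS_TABLE_VERSION = "iupac-conventional-2021/principal-isotope-1.0"

# symbol -> (atomic number, conventional atomic weight g/mol,
#            principal-isotope mass Da)
_ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H":  (1,  1.008,       1.00782503207),
    "He": (2,  4.002602,    4.002603254),
    "B":  (5,  10.81,       11.009305),
    "C":  (6,  12.011,      12.0),
    "N":  (7,  14.007,      14.0030740048),
    "O":  (8,  15.999,      15.9949146196),
    "F":  (9,  18.998403163, 18.9984031627),
    "Na": (11, 22.98976928, 22.9897692820),
    "Mg": (12, 24.305,      23.985041697),
    "Al": (13, 26.9815384,  26.98153853),
    "Si": (14, 28.085,      27.97692653465),
    "P":  (15, 30.973761998, 30.97376199842),
    "S":  (16, 32.06,       31.9720711744),
    "Cl": (17, 35.45,       34.96885268),
    "K":  (19, 39.0983,     38.9637064864),
    "Ca": (20, 40.078,      39.962590863),
    "Fe": (26, 55.845,      55.93493633),
    "Zn": (30, 65.38,       63.92914201),
    "Br": (35, 79.904,      78.9183376),
    "I":  (53, 126.90447,   126.904473),
    "Ar": (18, 39.948,      39.9623831237),
}

ATOMIC_NUMBER = {sym: z for sym, (z, _, _) in _ELEMENTS.items()}
SYMBOL_OF = {z: sym for sym, z in ATOMIC_NUMBER.items()}
AVERAGE_WEIGHT = {sym: w for sym, (_, w, _) in _ELEMENTS.items()}
PRINCIPAL_ISOTOPE_MASS = {sym: m for sym, (_, _, m) in _ELEMENTS.items()}

HALOGENS = frozenset({"F", "Cl", "Br", "I"})
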