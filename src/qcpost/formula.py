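"""Molecular-formula parsing and mass/composition descriptors.

Covers the quantities that accompany a synthesis characterization block:
average molar mass and elemental-analysis percentages ("Anal. Calcd."),
monoisotopic and adduct masses ("HRMS calcd"), and the two energetic-
material descriptors, nitrogen mass percentage and oxygen balance.

Formulas are plain element/count maps; no structural (SMILES/InChI)
information is handled. Canonical text output is Hill order: carbon,
then hydrogen, then the remaining elements alphabetically (all elements
alphabetical when carbon is absent).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

from . import constants as k

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "MassTables",
    "EnergeticDescriptors",
    "parse_formula",
    "format_formula",
    "average_molar_mass",
    "monoisotopic_mass",
    "adduct_mass",
    "elemental_percentages",
    "nitrogen_percent",
    "oxygen_balance",
    "round_half_even",
]


class FormulaError(ValueError):
    """Raised for unparseable formulas or unsupported elements."""


def round_half_even(x: float, ndigits: int) -> float:
    """Round to *ndigits* decimals with banker's (half-to-even) rounding.

    Report values are rounded this way; raw doubles are kept internally.
    Decimal quantization on the shortest repr avoids binary-float
    artifacts such as round(2.675, 2) -> 2.67.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> atom-count map, e.g. {C: 24, H: 16, N: 14, O: 10}."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("empty formula")
        for sym, n in self.counts.items():
            if sym not in k.ATOMIC_NUMBER:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __str__(self) -> str:
        return format_formula(self)

    def scaled(self, factor: int) -> "MolecularFormula":
        """Formula with every count multiplied by a positive integer."""
        if factor < 1:
            raise FormulaError("scale factor must be >= 1")
        return MolecularFormula({s: n * factor for s, n in self.counts.items()})


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C24H18Cl2N10O2"``.

    Each element symbol may be followed by a positive integer count;
    a missing count means 1. Symbols are case-sensitive. Repeated
    symbols accumulate.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in k.ATOMIC_NUMBER:
            raise FormulaError(f"unknown element symbol: {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def format_formula(formula: MolecularFormula) -> str:
    """Canonical Hill-order string; round-trips through parse_formula."""
    counts = formula.counts
    symbols: list[str] = []
    if "C" in counts:
        symbols.append("C")
        if "H" in counts:
            symbols.append("H")
        symbols.extend(sorted(s for s in counts if s not in ("C", "H")))
    else:
        symbols.extend(sorted(counts))
    return "".join(f"{s}{counts[s] if counts[s] > 1 else ''}" for s in symbols)


@dataclass(frozen=True)
class MassTables:
    """Versioned element-mass lookups used by every mass descriptor."""

    average_weight: dict[str, float] = field(
        default_factory=lambda: dict(k.AVERAGE_WEIGHT)
    )
    principal_isotope_mass: dict[str, float] = field(
        default_factory=lambda: dict(k.PRINCIPAL_ISOTOPE_MASS)
    )
    version: str = k.MASS_TABLE_VERSION


DEFAULT_TABLES = MassTables()


def _lookup(table: dict[str, float], sym: str, kind: str) -> float:
    try:
        return table[sym]
    except KeyError:
        raise FormulaError(f"no {kind} entry for element {sym!r}") from None


def average_molar_mass(
    formula: MolecularFormula, tables: MassTables = DEFAULT_TABLES
) -> float:
    """Standard (average) molar mass in g/mol."""
    return sum(
        n * _lookup(tables.average_weight, s, "atomic-weight")
        for s, n in formula.counts.items()
    )


def monoisotopic_mass(
    formula: MolecularFormula, tables: MassTables = DEFAULT_TABLES
) -> float:
    """Monoisotopic (all principal isotopes) mass in Da.

    This is the neutral exact mass quoted as "HRMS calcd" in high-
    resolution mass spectrometry.
    """
    return sum(
        n * _lookup(tables.principal_isotope_mass, s, "isotope-mass")
        for s, n in formula.counts.items()
    )


_ADDUCTS = ("M", "M+H", "M-H")


def adduct_mass(
    formula: MolecularFormula,
    adduct: str = "M",
    tables: MassTables = DEFAULT_TABLES,
    *,
    electron_correction: bool = True,
) -> float:
    """Monoisotopic mass of the neutral (M) or protonated/deprotonated ion.

    [M+H]+ adds one 1H and, by mass-spectrometry convention, subtracts
    one electron mass (i.e. adds a bare proton); [M−H]− is symmetric.
    ``electron_correction=False`` reproduces the laxer convention that
    adds/removes a neutral hydrogen atom.
    """
    adduct = adduct.replace("−", "-")
    if adduct not in _ADDUCTS:
        raise FormulaError(f"unsupported adduct {adduct!r}; expected one of {_ADDUCTS}")
    m = monoisotopic_mass(formula, tables)
    if adduct == "M":
        return m
    h = _lookup(tables.principal_isotope_mass, "H", "isotope-mass")
    e = k.ELECTRON_MASS_DA if electron_correction else 0.0
    delta = h - e
    return m + delta if adduct == "M+H" else m - delta


def elemental_percentages(
    formula: MolecularFormula, tables: MassTables = DEFAULT_TABLES
) -> dict[str, float]:
    """Mass percentage of each element (the "Anal. Calcd." quantities).

    Raw (unrounded) values; they sum to 100 to within accumulated
    floating-point error. Reports round half-to-even at 2 decimals.
    """
    mw = average_molar_mass(formula, tables)
    return {
        s: 100.0 * n * _lookup(tables.average_weight, s, "atomic-weight") / mw
        for s, n in formula.counts.items()
    }


def nitrogen_percent(
    formula: MolecularFormula, tables: MassTables = DEFAULT_TABLES
) -> float:
    """Nitrogen mass percentage; 0 for nitrogen-free formulas."""
    if formula["N"] == 0:
        return 0.0
    return elemental_percentages(formula, tables)["N"]


@dataclass(frozen=True)
class EnergeticDescriptors:
    """Energetic-material screening numbers for one formula."""

    nitrogen_percent: float
    oxygen_balance: float
    convention_tag: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.nitrogen_percent <= 100.0:
            raise ValueError("nitrogen percentage outside [0, 100]")


_OB_CONVENTIONS = ("CHNO-classic", "halogen-HX")


def oxygen_balance(
    formula: MolecularFormula,
    tables: MassTables = DEFAULT_TABLES,
    convention: str = "CHNO-classic",
) -> float:
    """Oxygen balance (%) relative to complete combustion to CO2 and H2O.

    OB% = 1600 (nO − 2 nC − nH/2) / MW. Under "CHNO-classic" halogens
    are simply ignored in the atom terms (they still contribute to MW);
    under "halogen-HX" each halogen atom is assumed to leave as HX, so
    the hydrogen term becomes (nH − nX)/2. Nitrogen leaves as N2 and
    never enters the balance. Negative values mean oxygen deficit.
    """
    if convention not in _OB_CONVENTIONS:
        raise FormulaError(
            f"unknown oxygen-balance convention {convention!r}; expected one of {_OB_CONVENTIONS}"
        )
    allowed = {"C", "H", "N", "O"} | k.HALOGENS
    bad = set(formula.counts) - allowed
    if bad:
        raise FormulaError(
            f"oxygen balance defined only over C/H/N/O and halogens; found {sorted(bad)}"
        )
    n_c, n_h, n_o = formula["C"], formula["H"], formula["O"]
    n_x = sum(formula[s] for s in k.HALOGENS)
    h_term = (n_h - n_x) / 2.0 if convention == "halogen-HX" else n_h / 2.0
    mw = average_molar_mass(formula, tables)
    return 1600.0 * (n_o - 2.0 * n_c - h_term) / mw


def energetic_descriptors(
    formula: MolecularFormula,
    tables: MassTables = DEFAULT_TABLES,
    convention: str = "CHNO-classic",
) -> EnergeticDescriptors:
    """Bundle nitrogen percentage and oxygen balance with the convention used."""
    return EnergeticDescriptors(
        nitrogen_percent=nitrogen_percent(formula, tables),
        oxygen_balance=oxygen_balance(formula, tables, convention),
        convention_tag=convention,
    )
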