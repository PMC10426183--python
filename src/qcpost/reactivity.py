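"""Global conceptual-DFT reactivity descriptors from frontier orbitals.

For a gapped closed-shell molecule the Koopmans-type estimates
I = −E_HOMO and A = −E_LUMO feed the standard descriptor set:

    χ = (I + A)/2        electronegativity
    µ = −χ               electronic chemical potential
    η = (I − A)/2        chemical hardness
    S = 1/(2η)           global softness
    ω = µ² / (2η)        electrophilicity index (Parr–Szentpály–Liu)

All descriptors inherit the unit system of the orbital energies
(hartree internally; eV at presentation). Softness carries inverse
energy units, so under a unit change it scales by the reciprocal
factor while I, A, χ, µ, η and ω scale linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import HARTREE_TO_EV

__all__ = [
    "ReactivityError",
    "OrbitalEnergies",
    "GlobalReactivity",
    "global_descriptors",
    "convert_energy",
    "series_ranking",
]

_UNITS = ("hartree", "eV")


class ReactivityError(ValueError):
    """Invalid orbital input (gapless state, unknown unit)."""


@dataclass(frozen=True)
class OrbitalEnergies:
    """Frontier orbital energies of a closed-shell ground state."""

    e_homo: float
    e_lumo: float
    unit: str = "hartree"

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ReactivityError(f"unknown energy unit {self.unit!r}")
        if not self.e_homo < self.e_lumo:
            raise ReactivityError(
                f"need e_homo < e_lumo for a gapped ground state; "
                f"got {self.e_homo} >= {self.e_lumo}"
            )


@dataclass(frozen=True)
class GlobalReactivity:
    """The full global descriptor set, in the unit system of the input.

    ``mu`` is the signed chemical potential (negative for bound
    systems); ``mu_abs`` is its magnitude, the form customarily printed
    in descriptor tables.
    """

    ionization_potential: float
    electron_affinity: float
    gap: float
    electronegativity: float
    mu: float
    mu_abs: float
    hardness: float
    softness: float
    electrophilicity: float
    unit: str = "hartree"


def global_descriptors(orbitals: OrbitalEnergies) -> GlobalReactivity:
    """Compute the descriptor set from one molecule's frontier energies.

    Raises ReactivityError on a degenerate (gapless) input, where
    hardness vanishes and softness/electrophilicity are undefined.
    """
    i = -orbitals.e_homo
    a = -orbitals.e_lumo
    gap = i - a  # == e_lumo - e_homo
    if gap <= 0.0:
        raise ReactivityError("zero hardness: e_homo == e_lumo (degenerate input)")
    chi = 0.5 * (i + a)
    mu = -chi
    eta = 0.5 * gap
    return GlobalReactivity(
        ionization_potential=i,
        electron_affinity=a,
        gap=gap,
        electronegativity=chi,
        mu=mu,
        mu_abs=abs(mu),
        hardness=eta,
        softness=1.0 / (2.0 * eta),
        electrophilicity=mu * mu / (2.0 * eta),
        unit=orbitals.unit,
    )


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between hartree and eV (27.211386 eV/hartree)."""
    for u in (from_unit, to_unit):
        if u not in _UNITS:
            raise ReactivityError(f"unknown energy unit {u!r}")
    if from_unit == to_unit:
        return value
    return value * HARTREE_TO_EV if from_unit == "hartree" else value / HARTREE_TO_EV


def series_ranking(
    records: list[tuple[str, GlobalReactivity]],
) -> dict[str, list[str]]:
    """Order a compound series by each headline descriptor.

    Returns, for each key, compound ids from most to least extreme:
    ``softest`` (descending softness), ``hardest`` (descending
    hardness), ``most_electrophilic`` (descending ω) and
    ``lowest_ionization`` (ascending I). Ties break on lexicographic
    compound id, so the ordering is deterministic.
    """
    if not records:
        raise ReactivityError("empty record list")

    def order(key, reverse: bool) -> list[str]:
        if reverse:
            return [cid for cid, _ in sorted(records, key=lambda r: (-key(r[1]), r[0]))]
        return [cid for cid, _ in sorted(records, key=lambda r: (key(r[1]), r[0]))]

    return {
        "softest": order(lambda g: g.softness, reverse=True),
        "hardest": order(lambda g: g.hardness, reverse=True),
        "most_electrophilic": order(lambda g: g.electrophilicity, reverse=True),
        "lowest_ionization": order(lambda g: g.ionization_potential, reverse=False),
    }
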