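"""Ideal-gas rigid-rotor / harmonic-oscillator (RRHO) thermochemistry.

Statistical-thermodynamic functions S(T), H(T) and G(T) from harmonic
vibrational wavenumbers plus molecular mass and rotational constants,
on a temperature grid (default 10-500 K). Standard textbook partition
functions:

  translation  Sackur-Tetrode at the stored pressure, E = 3/2 RT
  rotation     classical rigid rotor (linear or asymmetric top) with
               symmetry number sigma, E = RT or 3/2 RT
  vibration    independent harmonic modes, theta = h c nu / k_B;
               ZPE inclusion is a recorded toggle
  electronic   R ln g degeneracy term, no excited states

H(T) is reported relative to 0 K; G(T) = H(T) - T S(T). Entropies in
J mol^-1 K^-1, enthalpy and Gibbs energy in kJ mol^-1. No anharmonic,
hindered-rotor or QRRHO corrections are applied by default; a QRRHO
low-frequency interpolation (Grimme-style) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ATM_PA, AVOGADRO, BOLTZMANN, C2_CM_K, GAS_CONSTANT, PLANCK

__all__ = [
    "ThermoError",
    "VibrationalSet",
    "RigidBody",
    "ThermoProfile",
    "vibrational_terms",
    "translational_rotational_terms",
    "thermo_profile",
    "default_grid",
]

log = logging.getLogger(__name__)

R = GAS_CONSTANT
_X_MAX = 500.0  # beyond this, thermal mode contributions underflow to 0


class ThermoError(ValueError):
    """Invalid thermochemistry input."""


@dataclass(frozen=True)
class VibrationalSet:
    """Positive harmonic wavenumbers (cm^-1); imaginary modes dropped.

    Construct via :meth:`from_raw` to filter a raw frequency list:
    non-positive (imaginary) values are discarded with a logged
    warning and counted in ``dropped_imaginary``.
    """

    frequencies: tuple[float, ...]
    dropped_imaginary: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.frequencies):
            raise ThermoError("retained frequencies must all be positive")

    @classmethod
    def from_raw(cls, values) -> "VibrationalSet":
        vals = [float(v) for v in values]
        kept = tuple(v for v in vals if v > 0)
        dropped = len(vals) - len(kept)
        if dropped:
            log.warning("dropped %d non-positive (imaginary) frequencies", dropped)
        return cls(frequencies=kept, dropped_imaginary=dropped)

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def zpe(self) -> float:
        """Zero-point vibrational energy, J/mol: sum R*theta/2."""
        theta = C2_CM_K * np.asarray(self.frequencies)
        return float(0.5 * R * theta.sum())


@dataclass(frozen=True)
class RigidBody:
    """Mass, rotation and state data for translation/rotation terms."""

    molar_mass: float  # g/mol
    rotational_constants: tuple[float, ...] = ()  # GHz; 3 values, or 1 if linear
    symmetry_number: int = 1
    pressure: float = ATM_PA  # Pa
    electronic_degeneracy: int = 1
    linear: bool = False

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ThermoError("molar mass must be positive")
        if self.symmetry_number < 1:
            raise ThermoError("symmetry number must be >= 1")
        if self.pressure <= 0:
            raise ThermoError("pressure must be positive")
        if self.electronic_degeneracy < 1:
            raise ThermoError("electronic degeneracy must be >= 1")
        n_expected = 1 if self.linear else 3
        if self.rotational_constants and len(self.rotational_constants) != n_expected:
            raise ThermoError(
                f"expected {n_expected} rotational constants, got {len(self.rotational_constants)}"
            )
        if any(b <= 0 for b in self.rotational_constants):
            raise ThermoError("rotational constants must be positive")


def _check_temperature(T: float) -> None:
    if T <= 0:
        raise ThermoError(f"temperature must be positive, got {T}")


def _qrrho_weight(nu: np.ndarray, nu0: float = 100.0, alpha: int = 4) -> np.ndarray:
    """Head-Gordon damping function w(nu) for QRRHO entropy interpolation."""
    return 1.0 / (1.0 + (nu0 / nu) ** alpha)


def vibrational_terms(
    vib: VibrationalSet,
    T: float,
    *,
    include_zpe: bool = True,
    qrrho: bool = False,
) -> tuple[float, float, float]:
    """(S_vib, E_vib, Cv_vib) at temperature T.

    Per mode, with x = theta/T = h c nu / (k_B T):

        S  = R [ x/(e^x - 1) - ln(1 - e^-x) ]
        E  = R theta [ 1/2 + 1/(e^x - 1) ]     (the 1/2 is the ZPE term)
        Cv = R x^2 e^x / (e^x - 1)^2

    Units: S, Cv in J mol^-1 K^-1; E in J mol^-1. With ``qrrho`` the
    entropy of each mode is interpolated toward a free-rotor value for
    low frequencies (Grimme/Head-Gordon damping at 100 cm^-1).
    """
    _check_temperature(T)
    if len(vib) == 0:
        return 0.0, 0.0, 0.0
    nu = np.asarray(vib.frequencies)
    theta = C2_CM_K * nu
    x = np.minimum(theta / T, _X_MAX)
    em = np.expm1(x)  # e^x - 1, accurate for small x
    s_ho = R * (x / em - np.log1p(-np.exp(-x)))
    e_thermal = R * theta / em
    # e^x/(e^x-1)^2 written as e^-x/(1-e^-x)^2 to avoid overflow at large x
    cv = R * x * x * np.exp(-x) / np.expm1(-x) ** 2

    if qrrho:
        # free-rotor entropy of an effective rotor with mu' capped by B_av
        b_av = 1e-44  # kg m^2, conventional averaging moment
        mu_eff = PLANCK / (8 * np.pi**2 * (nu * 2.99792458e10))
        mu_p = mu_eff * b_av / (mu_eff + b_av)
        s_fr = R * (0.5 + np.log(np.sqrt(8 * np.pi**3 * mu_p * BOLTZMANN * T) / PLANCK))
        w = _qrrho_weight(nu)
        s_modes = w * s_ho + (1.0 - w) * s_fr
    else:
        s_modes = s_ho

    e = float(e_thermal.sum())
    if include_zpe:
        e += vib.zpe
    return float(s_modes.sum()), e, float(cv.sum())


def translational_rotational_terms(
    body: RigidBody, T: float
) -> tuple[float, float, float, float]:
    """(S_trans, S_rot, E_trans, E_rot) at temperature T.

    S_trans is Sackur-Tetrode at the body's stored pressure; S_rot the
    classical rigid-rotor result (0 for an atom, i.e. no rotational
    constants). Energies are equipartition values in J/mol.
    """
    _check_temperature(T)
    m = body.molar_mass * 1e-3 / AVOGADRO  # kg per molecule
    lam3 = (2.0 * np.pi * m * BOLTZMANN * T / PLANCK**2) ** 1.5
    q_trans = lam3 * BOLTZMANN * T / body.pressure
    s_trans = R * (np.log(q_trans) + 2.5)
    e_trans = 1.5 * R * T

    if not body.rotational_constants:
        return float(s_trans), 0.0, float(e_trans), 0.0

    # characteristic rotational temperatures from B in GHz
    thetas = [PLANCK * b * 1e9 / BOLTZMANN for b in body.rotational_constants]
    sigma = body.symmetry_number
    if body.linear:
        q_rot = T / (sigma * thetas[0])
        s_rot = R * (1.0 + np.log(q_rot))
        e_rot = R * T
    else:
        q_rot = np.sqrt(np.pi) / sigma * np.sqrt(T**3 / np.prod(thetas))
        s_rot = R * (1.5 + np.log(q_rot))
        e_rot = 1.5 * R * T
    return float(s_trans), float(s_rot), float(e_trans), float(e_rot)


@dataclass(frozen=True)
class ThermoProfile:
    """S(T), H(T), G(T) over a temperature grid, with the toggles used."""

    temperatures: np.ndarray  # K
    entropy: np.ndarray       # J mol^-1 K^-1
    enthalpy: np.ndarray      # kJ mol^-1, relative to 0 K
    gibbs: np.ndarray         # kJ mol^-1
    zpe_included: bool = True
    qrrho: bool = False
    pressure: float = ATM_PA
    metadata: dict = field(default_factory=dict)

    def to_frame(self, compound_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "T_K": self.temperatures,
                "S_J_per_molK": self.entropy,
                "H_kJ_per_mol": self.enthalpy,
                "G_kJ_per_mol": self.gibbs,
            }
        )
        if compound_id is not None:
            df.insert(0, "compound", compound_id)
        return df


def default_grid(tmin: float = 10.0, tmax: float = 500.0, step: float = 10.0) -> np.ndarray:
    """Inclusive temperature grid, 10-500 K in 10 K steps by default."""
    n = int(round((tmax - tmin) / step)) + 1
    return tmin + step * np.arange(n)


def thermo_profile(
    vib: VibrationalSet,
    body: RigidBody,
    grid=None,
    *,
    include_zpe: bool = True,
    qrrho: bool = False,
) -> ThermoProfile:
    """Total S, H, G over a temperature grid.

    S = S_trans + S_rot + S_vib + R ln g;  H = E_trans + E_rot + E_vib
    + RT (ideal-gas PV term), relative to 0 K;  G = H - T S.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ThermoError("empty temperature grid")
    if (grid <= 0).any():
        raise ThermoError("grid temperatures must be positive")
    if (np.diff(grid) <= 0).any():
        raise ThermoError("grid must be sorted ascending without duplicates")

    s_el = R * np.log(body.electronic_degeneracy)
    s_tot = np.empty_like(grid)
    h_tot = np.empty_like(grid)
    for i, T in enumerate(grid):
        s_v, e_v, _ = vibrational_terms(vib, T, include_zpe=include_zpe, qrrho=qrrho)
        s_t, s_r, e_t, e_r = translational_rotational_terms(body, T)
        s_tot[i] = s_t + s_r + s_v + s_el
        h_tot[i] = (e_t + e_r + e_v + R * T) / 1000.0  # kJ/mol
    g_tot = h_tot - grid * s_tot / 1000.0
    return ThermoProfile(
        temperatures=grid,
        entropy=s_tot,
        enthalpy=h_tot,
        gibbs=g_tot,
        zpe_included=include_zpe,
        qrrho=qrrho,
        pressure=body.pressure,
        metadata={"n_modes": len(vib), "dropped_imaginary": vib.dropped_imaginary},
    )
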