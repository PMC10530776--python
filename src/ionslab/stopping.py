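"""Stopping power and range physics for light ions in compound materials.

Electronic stopping uses the relativistic Bethe formula with a Barkas-type
effective projectile charge and Bragg additivity over the elements of a
compound (mean excitation energy combined as ln I = sum f_i Z_i ln I_i /
sum f_i Z_i).  Below 0.25 MeV/u the Bethe logarithm is unreliable and
stopping is continued with velocity-proportional scaling matched at the
join; only the last few micrometres of a therapy-energy track are affected.

Nuclear (elastic) stopping uses the ZBL universal screening function.  At
therapy energies it is several orders of magnitude below the electronic
component but it drives the recoil observables near the end of range.

Energy-loss straggling follows the Bohr model: the variance accumulated
per unit path length is proportional to the electron density and the
square of the effective projectile charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import ELEMENTS, Material

__all__ = [
    "ProjectileSpec",
    "helium",
    "VALID_ENERGY_MEV",
    "effective_charge",
    "electronic_stopping",
    "nuclear_stopping",
    "straggling_variance_per_length",
    "csda_range",
    "radiation_length_mm",
    "StoppingTable",
    "zbl_reduced_energy",
    "zbl_reduced_stopping",
    "zbl_stopping_single",
    "lss_electronic_single",
]

AMU_MEV = 931.494               # atomic mass unit in MeV/c^2
TWO_ME_C2_EV = 1.021998e6       # 2 m_e c^2 in eV
BETHE_K = 5.0989e-25            # 4 pi r_e^2 m_e c^2 in MeV cm^2 (per e-/cm^3)
E2_EV_A = 14.3996               # e^2 in eV * Angstrom

# Validated projectile kinetic-energy window (total MeV for 4He).
VALID_ENERGY_MEV = (0.1, 500.0)

# Below this specific energy the Bethe logarithm is continued with
# velocity-proportional (Lindhard-Scharff-like) scaling.
_JOIN_MEV_PER_U = 0.25


@dataclass(frozen=True)
class ProjectileSpec:
    """Projectile ion: charge number, mass (amu) and kinetic energy (MeV)."""

    Z1: int = 2
    A1: float = 4.0026
    energy_MeV: float = 354.0

    def __post_init__(self) -> None:
        if self.Z1 < 1:
            raise ValueError(f"Z1 must be >= 1, got {self.Z1}")
        if self.energy_MeV <= 0:
            raise ValueError(f"energy must be > 0, got {self.energy_MeV}")


def helium(energy_MeV: float) -> ProjectileSpec:
    """A 4He projectile at the given kinetic energy."""
    return ProjectileSpec(Z1=2, A1=4.0026, energy_MeV=energy_MeV)


def _check_energy(energy_MeV: float) -> None:
    lo, hi = VALID_ENERGY_MEV
    if not lo <= energy_MeV <= hi:
        raise ValueError(
            f"projectile energy {energy_MeV} MeV outside validated range "
            f"[{lo}, {hi}] MeV"
        )


def _beta2_gamma2(energy_MeV, A1: float):
    """Relativistic beta^2 and gamma^2 for kinetic energy per ion."""
    M = A1 * AMU_MEV
    gamma = 1.0 + np.asarray(energy_MeV, dtype=float) / M
    beta2 = 1.0 - 1.0 / gamma**2
    return beta2, gamma**2


def effective_charge(Z1: int, beta: np.ndarray | float) -> np.ndarray | float:
    """Barkas-type effective charge Z1*(1 - exp(-125 beta / Z1^(2/3)))."""
    return Z1 * (1.0 - np.exp(-125.0 * np.asarray(beta, dtype=float) / Z1 ** (2.0 / 3.0)))


def _bethe_eV_per_A(energy_MeV: np.ndarray, material: Material,
                    Z1: int, A1: float) -> np.ndarray:
    """Bethe electronic stopping in eV/Angstrom, with low-energy join."""
    E = np.atleast_1d(np.asarray(energy_MeV, dtype=float))
    join = _JOIN_MEV_PER_U * A1
    E_eval = np.maximum(E, join)
    beta2, gamma2 = _beta2_gamma2(E_eval, A1)
    zeff = effective_charge(Z1, np.sqrt(beta2))
    I_eV = material.mean_excitation_energy_eV
    arg = TWO_ME_C2_EV * beta2 * gamma2 / I_eV
    L = np.log(arg) - beta2
    n_e = material.electron_density_cm3
    S_MeV_cm = BETHE_K * n_e * zeff**2 / beta2 * L
    S = S_MeV_cm * 0.01  # MeV/cm -> eV/A
    # velocity-proportional continuation below the join energy
    low = E < join
    if np.any(low):
        S = np.where(low, S * np.sqrt(E / join), S)
    return S


def electronic_stopping(projectile: ProjectileSpec, material: Material) -> float:
    """Electronic stopping power S_e in eV/Angstrom."""
    _check_energy(projectile.energy_MeV)
    return float(_bethe_eV_per_A(projectile.energy_MeV, material,
                                 projectile.Z1, projectile.A1)[0])


# ---------------------------------------------------------------------------
# ZBL universal nuclear stopping
# ---------------------------------------------------------------------------

def zbl_reduced_energy(Z1: int, m1: float, Z2: int, m2: float,
                       energy_eV) -> np.ndarray:
    """ZBL reduced energy epsilon for a (Z1, m1) ion on a (Z2, m2) atom."""
    E_keV = np.asarray(energy_eV, dtype=float) / 1e3
    return (32.53 * m2 * E_keV
            / (Z1 * Z2 * (m1 + m2) * (Z1**0.23 + Z2**0.23)))


def zbl_reduced_stopping(eps) -> np.ndarray:
    """ZBL universal reduced nuclear stopping s_n(epsilon)."""
    eps = np.asarray(eps, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        low = (np.log1p(1.1383 * eps)
               / (2.0 * (eps + 0.01321 * eps**0.21226 + 0.19593 * np.sqrt(eps))))
        high = np.log(eps) / (2.0 * eps)
    out = np.where(eps <= 30.0, low, high)
    return np.where(eps > 0, out, 0.0)


def zbl_stopping_single(Z1: int, m1: float, Z2: int, m2: float,
                        energy_eV, n_cm3: float) -> np.ndarray:
    """ZBL nuclear stopping (eV/Angstrom) in a single-element target."""
    eps = zbl_reduced_energy(Z1, m1, Z2, m2, energy_eV)
    sn = zbl_reduced_stopping(eps)
    # eV cm^2 per 1e15 atoms
    per_atom = 8.462 * Z1 * Z2 * m1 * sn / ((m1 + m2) * (Z1**0.23 + Z2**0.23))
    return per_atom * n_cm3 * 1e-15 * 1e-8  # -> eV/A


def lss_electronic_single(Z1: int, m1: float, Z2: int,
                          energy_eV, n_cm3: float) -> np.ndarray:
    """Lindhard-Scharff velocity-proportional electronic stopping (eV/A).

    Intended for slow (keV-scale) recoil atoms, e.g. when locating the
    energy at which electronic losses overtake nuclear ones.
    """
    E_keV = np.asarray(energy_eV, dtype=float) / 1e3
    k = 3.83 * Z1 ** (7.0 / 6.0) * Z2 / (Z1 ** (2.0 / 3.0) + Z2 ** (2.0 / 3.0)) ** 1.5
    per_atom = k * np.sqrt(np.maximum(E_keV, 0.0) / m1)
    return per_atom * n_cm3 * 1e-15 * 1e-8


def _zbl_eV_per_A(energy_MeV: np.ndarray, material: Material,
                  Z1: int, A1: float) -> np.ndarray:
    E_eV = np.atleast_1d(np.asarray(energy_MeV, dtype=float)) * 1e6
    total = np.zeros_like(E_eV)
    for e in material.elements:
        n_i = material.atomic_density_cm3 * e.atomic_fraction
        total += zbl_stopping_single(Z1, A1, e.Z, e.A, E_eV, n_i)
    return total


def nuclear_stopping(projectile: ProjectileSpec, material: Material) -> float:
    """ZBL universal nuclear stopping S_n in eV/Angstrom (summed over elements)."""
    _check_energy(projectile.energy_MeV)
    return float(_zbl_eV_per_A(projectile.energy_MeV, material,
                               projectile.Z1, projectile.A1)[0])


def straggling_variance_per_length(projectile: ProjectileSpec,
                                   material: Material) -> float:
    """Bohr energy-loss straggling variance per path length, eV^2/Angstrom."""
    _check_energy(projectile.energy_MeV)
    beta2, _ = _beta2_gamma2(projectile.energy_MeV, projectile.A1)
    zeff = effective_charge(projectile.Z1, float(np.sqrt(beta2)))
    n_e_A3 = material.electron_density_cm3 * 1e-24  # electrons per A^3
    return float(4.0 * np.pi * E2_EV_A**2 * zeff**2 * n_e_A3)


def csda_range(projectile: ProjectileSpec, material: Material,
               cutoff_MeV: float = 0.1, n_points: int = 4000) -> float:
    """CSDA range in mm: integral of dE/(S_e+S_n) from cutoff to the energy."""
    _check_energy(projectile.energy_MeV)
    if projectile.energy_MeV <= cutoff_MeV:
        return 0.0
    E = np.geomspace(cutoff_MeV, projectile.energy_MeV, n_points)
    S = (_bethe_eV_per_A(E, material, projectile.Z1, projectile.A1)
         + _zbl_eV_per_A(E, material, projectile.Z1, projectile.A1))
    R_A = np.trapezoid(1.0 / S, E * 1e6)
    return float(R_A * 1e-7)  # Angstrom -> mm


def radiation_length_mm(material: Material) -> float:
    """Radiation length X0 in mm (Tsai approximation, mass-fraction mixing)."""
    mass_total = sum(e.atomic_fraction * e.A for e in material.elements)
    inv_X0 = 0.0  # in cm^2/g
    for e in material.elements:
        w_i = e.atomic_fraction * e.A / mass_total
        X0_i = 716.408 * e.A / (e.Z * (e.Z + 1.0) * np.log(287.0 / np.sqrt(e.Z)))
        inv_X0 += w_i / X0_i
    X0_gcm2 = 1.0 / inv_X0
    return float(X0_gcm2 / material.mass_density * 10.0)  # cm -> mm


@dataclass(frozen=True)
class StoppingTable:
    """Tabulated stopping for one material on a log energy grid."""

    material: Material
    energy_MeV: np.ndarray
    S_e: np.ndarray            # eV/A
    S_n: np.ndarray            # eV/A
    straggling_eV2_per_A: np.ndarray

    @classmethod
    def build(cls, material: Material, Z1: int = 2, A1: float = 4.0026,
              n_points: int = 1024,
              e_min: float = VALID_ENERGY_MEV[0],
              e_max: float = VALID_ENERGY_MEV[1]) -> "StoppingTable":
        E = np.geomspace(e_min, e_max, n_points)
        S_e = _bethe_eV_per_A(E, material, Z1, A1)
        S_n = _zbl_eV_per_A(E, material, Z1, A1)
        beta2, _ = _beta2_gamma2(E, A1)
        zeff = effective_charge(Z1, np.sqrt(beta2))
        n_e_A3 = material.electron_density_cm3 * 1e-24
        strag = 4.0 * np.pi * E2_EV_A**2 * zeff**2 * n_e_A3 * np.ones_like(E)
        return cls(material, E, S_e, S_n, strag)

    def to_csv(self, dest) -> None:
        """CSV export: energy_MeV, S_e_eV_per_A, S_n_eV_per_A, range_mm."""
        import pandas as pd

        S = self.S_e + self.S_n
        # cumulative CSDA range along the tabulated grid
        r_A = np.concatenate(
            ([0.0], np.cumsum(np.diff(self.energy_MeV * 1e6)
                              * 0.5 * (1.0 / S[1:] + 1.0 / S[:-1])))
        )
        df = pd.DataFrame(
            {
                "energy_MeV": self.energy_MeV,
                "S_e_eV_per_A": self.S_e,
                "S_n_eV_per_A": self.S_n,
                "range_mm": r_A * 1e-7,
            }
        )
        df.to_csv(dest, index=False)
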