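"""Displacement-damage models: Kinchin-Pease, NRT, and recoil tallies.

The Kinchin-Pease (K-P) hard-sphere cascade model gives the expected
number of permanently displaced atoms produced by a primary knock-on atom
(PKA) of energy ``T`` given a threshold displacement energy ``E_d`` and an
electronic-stopping cutoff ``E_c``:

    nu(T) = 0            for T < E_d
            1            for E_d <= T < 2 E_d
            T / (2 E_d)  for 2 E_d <= T < E_c
            E_c / (2 E_d) for T >= E_c

The closed form is exact for the hard-sphere energy-sharing kernel in
which a moving atom of energy T transfers a uniformly distributed share
epsilon in (0, T) per collision; :func:`cascade_oracle` simulates that
kernel directly and is used as an independent convergence check.

The Norgett-Robinson-Torrens (NRT) refinement applies a displacement
efficiency of 0.8 to the damage energy:

    N_v(E_v) = 0                      for E_v < E_d
               1                      for E_d <= E_v < 2.5 E_d
               0.8 E_v / (2 E_d)      for E_v >= 2.5 E_d

which is continuous at E_v = 2.5 E_d.  Here the damage energy is taken
equal to the PKA energy (no Lindhard partition correction).

Default threshold: E_d = 25 eV for every element — a standard
displacement-threshold scale; measured values for tissue compounds do not
exist.  The default electronic cutoff E_c is the energy at which
electronic (Lindhard-Scharff) stopping of the recoiling atom overtakes its
nuclear (ZBL) stopping in the host material, solved per element and
cached.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .materials import ELEMENTS, Material
from .stopping import lss_electronic_single, zbl_stopping_single

__all__ = [
    "KPModel",
    "NRTModel",
    "RecoilEvent",
    "RecoilTally",
    "kp_displacements",
    "nrt_displacements",
    "cascade_oracle",
    "tally_recoils",
    "electronic_cutoff_energy",
    "kp_model_for",
]

DEFAULT_E_D_EV = 25.0


@dataclass(frozen=True)
class KPModel:
    """Kinchin-Pease parameters: threshold E_d and electronic cutoff E_c (eV)."""

    E_d: float = DEFAULT_E_D_EV
    E_c: float = 30_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.E_d < self.E_c:
            raise ValueError(
                f"require 0 < E_d < E_c, got E_d={self.E_d}, E_c={self.E_c}"
            )


@dataclass(frozen=True)
class NRTModel:
    """NRT parameters: threshold E_d (eV) and displacement efficiency."""

    E_d: float = DEFAULT_E_D_EV
    efficiency: float = 0.8

    def __post_init__(self) -> None:
        if self.E_d <= 0:
            raise ValueError(f"E_d must be > 0, got {self.E_d}")


@dataclass(frozen=True)
class RecoilEvent:
    """One PKA: depth of the collision, struck element, recoil energy."""

    depth_mm: float
    element: str
    T_eV: float

    def __post_init__(self) -> None:
        if self.T_eV < 0:
            raise ValueError(f"PKA energy must be >= 0, got {self.T_eV}")


def kp_displacements(T_eV, model: KPModel):
    """Expected K-P displacement count nu(T); scalar in, scalar out."""
    T = np.asarray(T_eV, dtype=float)
    if np.any(T < 0):
        raise ValueError("PKA energy T must be >= 0")
    out = np.where(
        T < model.E_d, 0.0,
        np.where(T < 2.0 * model.E_d, 1.0,
                 np.where(T < model.E_c, T / (2.0 * model.E_d),
                          model.E_c / (2.0 * model.E_d))))
    return float(out) if np.isscalar(T_eV) else out


def nrt_displacements(E_v_eV, model: NRTModel):
    """NRT displacement count N_v(E_v); scalar in, scalar out."""
    E_v = np.asarray(E_v_eV, dtype=float)
    if np.any(E_v < 0):
        raise ValueError("damage energy E_v must be >= 0")
    out = np.where(
        E_v < model.E_d, 0.0,
        np.where(E_v < 2.5 * model.E_d, 1.0,
                 model.efficiency * E_v / (2.0 * model.E_d)))
    return float(out) if np.isscalar(E_v_eV) else out


def cascade_oracle(T_eV: float, E_d_eV: float, n_trials: int,
                   seed: int = 0) -> tuple[float, np.ndarray]:
    """Direct hard-sphere cascade simulation (test oracle, not production).

    Each trial starts one moving atom at energy T.  A moving atom with
    energy >= 2 E_d collides, transferring epsilon ~ U(0, T); both the
    degraded atom (T - epsilon) and the struck atom (epsilon) continue the
    cascade.  An atom whose energy lands in [E_d, 2 E_d) counts as exactly
    one displacement; below E_d it contributes nothing.  Returns the mean
    displacement count and the per-trial counts.
    """
    if T_eV <= 0:
        raise ValueError("T must be > 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    counts = np.zeros(n_trials)
    energies = np.full(n_trials, float(T_eV))
    trial = np.arange(n_trials)
    while energies.size:
        low = energies < E_d_eV
        one = (energies >= E_d_eV) & (energies < 2.0 * E_d_eV)
        if np.any(one):
            np.add.at(counts, trial[one], 1.0)
        split = ~(low | one)
        energies = energies[split]
        trial = trial[split]
        if energies.size == 0:
            break
        eps = rng.random(energies.size) * energies
        energies = np.concatenate([energies - eps, eps])
        trial = np.concatenate([trial, trial])
    return float(counts.mean()), counts


@dataclass
class RecoilTally:
    """Whole-track recoil bookkeeping (published recoil-table analog)."""

    total_recoil_eV_per_A_ion: float
    contributions_pct: dict[str, float]     # per-element % of total energy
    displacements: dict[str, float]         # sum of nu(T) per element

    @property
    def contributions_sum(self) -> float:
        return sum(self.contributions_pct.values())


def tally_recoils(events, path_length_A: float, n_ions: int,
                  kp: KPModel | None = None) -> RecoilTally:
    """Aggregate PKA events into a whole-track recoil tally.

    ``events`` may be an iterable of :class:`RecoilEvent` or a
    :class:`~ionslab.transport.RecoilEventArrays`.  The total is
    ``sum(T) / (path_length * n_ions)`` in eV/(Angstrom * ion); per-element
    contributions are percentages of the summed recoil energy; an empty
    event collection yields a zero tally.
    """
    if path_length_A <= 0:
        raise ValueError("path_length must be > 0")
    if n_ions < 1:
        raise ValueError("n_ions must be >= 1")
    kp = kp or KPModel()
    if hasattr(events, "T_eV") and hasattr(events, "element"):
        T = np.asarray(events.T_eV, dtype=float)
        elems = np.asarray(events.element, dtype=object)
    else:
        T = np.array([e.T_eV for e in events], dtype=float)
        elems = np.array([e.element for e in events], dtype=object)
    if T.size == 0:
        return RecoilTally(0.0, {}, {})
    total_T = float(T.sum())
    contributions: dict[str, float] = {}
    displacements: dict[str, float] = {}
    nu = kp_displacements(T, kp)
    for sym in dict.fromkeys(elems.tolist()):       # first-seen order
        sel = elems == sym
        contributions[sym] = 100.0 * float(T[sel].sum()) / total_T
        displacements[sym] = float(nu[sel].sum())
    return RecoilTally(total_T / (path_length_A * n_ions),
                       contributions, displacements)


@lru_cache(maxsize=256)
def _cutoff_cached(symbol: str, mat_key: tuple) -> float:
    Z2, A2, _ = ELEMENTS[symbol]
    # host composition: (symbol, fraction) pairs + atomic density
    elems, n_tot_cm3 = mat_key
    E = np.geomspace(10.0, 1e7, 2000)   # eV
    S_e = np.zeros_like(E)
    S_n = np.zeros_like(E)
    for sym_t, frac in elems:
        Zt, At, _ = ELEMENTS[sym_t]
        n_i = n_tot_cm3 * frac
        S_e += lss_electronic_single(Z2, A2, Zt, E, n_i)
        S_n += zbl_stopping_single(Z2, A2, Zt, At, E, n_i)
    diff = S_e - S_n
    idx = np.nonzero(diff > 0)[0]
    if idx.size == 0:
        return float(E[-1])
    i = idx[0]
    if i == 0:
        return float(E[0])
    # linear interpolation of the sign change in log E
    f = diff[i - 1] / (diff[i - 1] - diff[i])
    return float(np.exp(np.log(E[i - 1]) + f * (np.log(E[i]) - np.log(E[i - 1]))))


def electronic_cutoff_energy(symbol: str, material: Material) -> float:
    """E_c (eV): energy where a recoiling atom's electronic stopping
    (Lindhard-Scharff) overtakes its nuclear (ZBL) stopping in the host
    material.  Cached per (element, material composition)."""
    if symbol not in ELEMENTS:
        raise ValueError(f"unknown element symbol {symbol!r}")
    key = (tuple((e.symbol, e.atomic_fraction) for e in material.elements),
           material.atomic_density_cm3)
    return _cutoff_cached(symbol, key)


def kp_model_for(symbol: str, material: Material,
                 E_d: float = DEFAULT_E_D_EV) -> KPModel:
    """K-P model for one element recoiling in a host material."""
    return KPModel(E_d=E_d, E_c=electronic_cutoff_energy(symbol, material))
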