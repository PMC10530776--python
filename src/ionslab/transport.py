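"""Condensed-history Monte Carlo transport of light ions through a slab phantom.

Each ion advances along +x from the entry surface.  Per step the engine
applies

* deterministic mean electronic energy loss (midpoint rule on the Bethe
  stopping table),
* a Gaussian Bohr-straggling perturbation of that loss,
* a Highland-model small-angle deflection of the direction vector
  (independent Gaussian kicks in the two transverse planes), and
* nuclear elastic collisions: transfers above a split energy are sampled
  as discrete Poisson events from a 1/T^2 screened-Rutherford spectrum
  (kinematically capped), transfers between the tally threshold and the
  split are deposited continuously with composition-weighted element
  attribution.

Steps are capped by a maximum fractional energy loss, by the depth-bin
width (so tallies stay smooth) and by the distance to the next layer
boundary (so no step spans two materials).  An ion terminates when its
energy falls below the low-energy cutoff — the residual is deposited
locally into the recoil tally — or when it leaves the stack (transmitted,
carrying its exit energy).  The whole ensemble is stepped in lock-step
with numpy; a fixed seed reproduces results bitwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .materials import Phantom
from .stopping import (
    AMU_MEV,
    E2_EV_A,
    ProjectileSpec,
    StoppingTable,
    VALID_ENERGY_MEV,
    _check_energy,
    radiation_length_mm,
)

__all__ = [
    "BeamSpec",
    "TransportConfig",
    "DepthDoseRecord",
    "TrackEnsemble",
    "RecoilEventArrays",
    "SimulationResult",
    "transport_ion",
    "run_simulation",
    "energy_scan",
    "default_scan_energies",
    "write_depth_dose_csv",
    "write_endpoints_csv",
]

MM_TO_A = 1.0e7


@dataclass(frozen=True)
class BeamSpec:
    """Beam definition: projectile, ensemble size and RNG seed."""

    projectile: ProjectileSpec
    n_ions: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ions < 1:
            raise ValueError(f"n_ions must be >= 1, got {self.n_ions}")


@dataclass(frozen=True)
class TransportConfig:
    """Numerical knobs of the condensed-history scheme."""

    step_fraction: float = 0.01          # max fractional energy loss per step
    n_depth_bins: int = 400
    recoil_threshold_eV: float = 10.0    # minimum tallied recoil energy
    discrete_recoil_split_eV: float = 1000.0  # discrete/continuous split
    low_energy_cutoff_MeV: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.step_fraction <= 0.05:
            raise ValueError("step_fraction must lie in (0, 0.05]")
        if self.n_depth_bins < 10:
            raise ValueError("n_depth_bins must be >= 10")
        if self.recoil_threshold_eV <= 0:
            raise ValueError("recoil_threshold_eV must be > 0")
        if self.discrete_recoil_split_eV < self.recoil_threshold_eV:
            raise ValueError("discrete split must be >= recoil threshold")


@dataclass
class DepthDoseRecord:
    """Depth-binned tallies, normalized per ion (eV/Angstrom/ion)."""

    depth_mm: np.ndarray               # bin centers
    ionization: np.ndarray             # electronic energy-loss density
    recoil_by_element: dict[str, np.ndarray]

    @property
    def recoil_total(self) -> np.ndarray:
        out = np.zeros_like(self.depth_mm)
        for arr in self.recoil_by_element.values():
            out = out + arr
        return out

    def to_frame(self):
        import pandas as pd

        data = {"depth_mm": self.depth_mm,
                "ionization_eV_per_A_per_ion": self.ionization,
                "recoil_eV_per_A_per_ion": self.recoil_total}
        for sym, arr in self.recoil_by_element.items():
            data[f"recoil_{sym}"] = arr
        return pd.DataFrame(data)


@dataclass
class TrackEnsemble:
    """Per-ion endpoint coordinates and stop flags."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    z_mm: np.ndarray
    stopped: np.ndarray                # bool; False = transmitted
    exit_energy_MeV: np.ndarray        # 0 for stopped ions

    @property
    def N(self) -> int:
        return int(self.x_mm.size)

    @property
    def R_p(self) -> float:
        """Mean projected range <x> over the full ensemble (mm)."""
        return float(np.sum(self.x_mm) / self.N)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"ion_id": np.arange(self.N),
             "x_mm": self.x_mm, "y_mm": self.y_mm, "z_mm": self.z_mm,
             "stopped": self.stopped.astype(int),
             "exit_energy_MeV": self.exit_energy_MeV}
        )


@dataclass
class RecoilEventArrays:
    """Discrete nuclear-collision events (primary knock-on atoms)."""

    depth_mm: np.ndarray
    element: np.ndarray                # element symbols (str array)
    T_eV: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.T_eV.size)


@dataclass
class SimulationResult:
    beam: BeamSpec
    config: TransportConfig
    phantom: Phantom
    depth_dose: DepthDoseRecord
    ensemble: TrackEnsemble
    recoil_events: RecoilEventArrays
    audit: dict
    provenance: dict

    @property
    def energy_MeV(self) -> float:
        return self.beam.projectile.energy_MeV

    @property
    def total_recoil_eV_per_A_ion(self) -> float:
        """Whole-track recoil energy density: sum(T)/(stack depth * N)."""
        binw_A = (self.depth_dose.depth_mm[1] - self.depth_dose.depth_mm[0]) * MM_TO_A
        depth_A = self.phantom.total_depth_mm * MM_TO_A
        return float(np.sum(self.depth_dose.recoil_total) * binw_A / depth_A)


# ---------------------------------------------------------------------------
# Precomputed per-phantom lookup tables
# ---------------------------------------------------------------------------

class _PhantomTables:
    """Log-energy-grid stopping/collision tables for every layer."""

    N_GRID = 1024

    def __init__(self, phantom: Phantom, projectile: ProjectileSpec,
                 config: TransportConfig):
        self.phantom = phantom
        self.symbols = phantom.element_symbols
        n_layers = len(phantom.layers)
        n_elem = len(self.symbols)
        Z1, A1 = projectile.Z1, projectile.A1
        e_min = 0.5 * config.low_energy_cutoff_MeV
        e_max = VALID_ENERGY_MEV[1]
        self.logE0 = np.log(e_min)
        self.dlogE = (np.log(e_max) - self.logE0) / (self.N_GRID - 1)
        E = np.exp(self.logE0 + self.dlogE * np.arange(self.N_GRID))
        self.E_grid = E

        self.Se = np.empty((n_layers, self.N_GRID))
        self.strag = np.empty((n_layers, self.N_GRID))
        self.X0_mm = np.empty(n_layers)
        self.lam_disc = np.zeros((n_layers, self.N_GRID))   # per Angstrom
        self.cont_rate = np.zeros((n_layers, self.N_GRID))  # eV per Angstrom
        self.cont_share = np.zeros((n_layers, n_elem))
        self.nk = np.zeros((n_layers, n_elem))              # n_i * k_i (eV/A)
        # kinematic factor gamma = 4 m1 m2/(m1+m2)^2 per global element
        from .materials import ELEMENTS

        self.gamma = np.array(
            [4.0 * A1 * ELEMENTS[s][1] / (A1 + ELEMENTS[s][1]) ** 2
             for s in self.symbols]
        )

        e4 = E2_EV_A**2
        T_split = config.discrete_recoil_split_eV
        T_thr = config.recoil_threshold_eV
        E_eV = E * 1e6
        for m, layer in enumerate(phantom.layers):
            mat = layer.material
            tab = StoppingTable.build(mat, Z1, A1, self.N_GRID, e_min, e_max)
            self.Se[m] = tab.S_e
            self.strag[m] = tab.straggling_eV2_per_A
            self.X0_mm[m] = radiation_length_mm(mat)
            for e in mat.elements:
                j = self.symbols.index(e.symbol)
                n_A3 = mat.atomic_density_cm3 * e.atomic_fraction * 1e-24
                k_i = np.pi * Z1**2 * e.Z**2 * e4 * (A1 / e.A)  # eV^2 A^2... /E -> eV A^2
                self.nk[m, j] = n_A3 * k_i
                Tmax = self.gamma[j] * E_eV
                # discrete channel: sigma(T > split)
                self.lam_disc[m] += (self.nk[m, j] / E_eV
                                     * np.clip(1.0 / T_split - 1.0 / Tmax, 0.0, None))
                # continuous channel: threshold < T < min(split, Tmax)
                upper = np.minimum(T_split, Tmax)
                self.cont_rate[m] += (self.nk[m, j] / E_eV
                                      * np.clip(np.log(upper / T_thr), 0.0, None))
                self.cont_share[m, j] = self.nk[m, j]
            norm = self.cont_share[m].sum()
            if norm > 0:
                self.cont_share[m] /= norm

        self.boundaries = np.asarray(phantom.boundaries_mm)

    def lookup(self, table: np.ndarray, m: np.ndarray, E_MeV: np.ndarray):
        """Log-linear interpolation of a (layer, grid) table."""
        t = (np.log(np.maximum(E_MeV, self.E_grid[0])) - self.logE0) / self.dlogE
        t = np.clip(t, 0.0, self.N_GRID - 1.000001)
        k = t.astype(np.int64)
        f = t - k
        flat = table.ravel()
        base = m * self.N_GRID + k
        return flat[base] * (1.0 - f) + flat[base + 1] * f


def _kinematics(E_MeV: np.ndarray, A1: float):
    M = A1 * AMU_MEV
    gamma = 1.0 + E_MeV / M
    beta2 = 1.0 - 1.0 / gamma**2
    pc = np.sqrt(E_MeV * (E_MeV + 2.0 * M))
    return beta2, pc


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def _run_ensemble(projectile: ProjectileSpec, phantom: Phantom,
                  config: TransportConfig, n_ions: int,
                  rng: np.random.Generator):
    tables = _PhantomTables(phantom, projectile, config)
    n_bins = config.n_depth_bins
    total_depth = phantom.total_depth_mm
    binw_mm = total_depth / n_bins
    binw_A = binw_mm * MM_TO_A
    cutoff = config.low_energy_cutoff_MeV
    T_split = config.discrete_recoil_split_eV
    Z1, A1 = projectile.Z1, projectile.A1
    n_layers = len(phantom.layers)
    n_elem = len(tables.symbols)

    # state
    E = np.full(n_ions, projectile.energy_MeV)          # MeV
    x = np.zeros(n_ions)
    y = np.zeros(n_ions)
    z = np.zeros(n_ions)
    uy = np.zeros(n_ions)
    uz = np.zeros(n_ions)
    alive = np.ones(n_ions, dtype=bool)
    stopped = np.zeros(n_ions, dtype=bool)
    exit_E = np.zeros(n_ions)

    ioniz = np.zeros(n_bins)                            # eV
    recoil_mat = np.zeros((n_layers, n_bins))           # eV, element-unresolved
    recoil_disc = np.zeros((n_elem, n_bins))            # eV, discrete events
    ev_depth: list[np.ndarray] = []
    ev_elem: list[np.ndarray] = []
    ev_T: list[np.ndarray] = []

    eps = 1e-9
    max_iter = 200_000
    for _ in range(max_iter):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        Ei = E[idx]
        xi = x[idx]
        m = np.clip(np.searchsorted(tables.boundaries, xi, side="right") - 1,
                    0, n_layers - 1)
        ux = np.sqrt(np.clip(1.0 - uy[idx]**2 - uz[idx]**2, 1e-4, None))

        Se0 = tables.lookup(tables.Se, m, Ei)
        ds_E = config.step_fraction * Ei * 1e6 / Se0 / MM_TO_A    # mm (path)
        dist_bnd = tables.boundaries[m + 1] - xi
        ds_bnd = dist_bnd / ux + eps
        ds = np.minimum(np.minimum(ds_E, binw_mm), np.maximum(ds_bnd, 1e-7))
        ds_A = ds * MM_TO_A

        # midpoint electronic loss + Bohr straggling
        E_mid = np.maximum(Ei - 0.5 * Se0 * ds_A * 1e-6, 0.5 * cutoff)
        Se_mid = tables.lookup(tables.Se, m, E_mid)
        var = tables.lookup(tables.strag, m, E_mid) * ds_A
        dE_e = Se_mid * ds_A + rng.standard_normal(idx.size) * np.sqrt(var)
        dE_e = np.clip(dE_e, 0.0, None)

        # continuous sub-split nuclear transfer
        dE_cont = tables.lookup(tables.cont_rate, m, E_mid) * ds_A

        # discrete nuclear collisions
        lam = tables.lookup(tables.lam_disc, m, E_mid) * ds_A
        counts = rng.poisson(lam)
        dE_disc = np.zeros(idx.size)
        hit = np.nonzero(counts)[0]
        if hit.size:
            rep = np.repeat(hit, counts[hit])            # event -> local row
            E_ev = Ei[rep] * 1e6                          # eV
            m_ev = m[rep]
            Tmax = tables.gamma[None, :] * E_ev[:, None]  # (n_ev, n_elem)
            w = tables.nk[m_ev] * np.clip(1.0 / T_split - 1.0 / Tmax, 0.0, None)
            wsum = w.sum(axis=1, keepdims=True)
            ok = wsum[:, 0] > 0
            if np.any(ok):
                rep = rep[ok]
                E_ev = E_ev[ok]
                w = w[ok] / wsum[ok]
                cdf = np.cumsum(w, axis=1)
                u = rng.random(rep.size)
                j = (u[:, None] > cdf).sum(axis=1)
                Tmax_j = tables.gamma[j] * E_ev
                v = rng.random(rep.size)
                T = T_split / (1.0 - v * (1.0 - T_split / Tmax_j))
                T = np.minimum(T, 0.9 * E_ev)
                depth_ev = np.clip(xi[rep] + 0.5 * ux[rep] * ds[rep],
                                   0.0, total_depth - eps)
                b_ev = np.minimum((depth_ev / binw_mm).astype(np.int64),
                                  n_bins - 1)
                np.add.at(recoil_disc, (j, b_ev), T)
                np.add.at(dE_disc, rep, T)
                ev_depth.append(depth_ev)
                ev_elem.append(j)
                ev_T.append(T)

        # energy bookkeeping (cap total loss at available energy)
        loss = dE_e + dE_cont + dE_disc
        over = loss - Ei * 1e6
        scale_mask = over > 0
        if np.any(scale_mask):
            red = np.minimum(dE_e[scale_mask], over[scale_mask])
            dE_e[scale_mask] -= red
            over[scale_mask] -= red
            dE_cont[scale_mask] = np.clip(dE_cont[scale_mask] - over[scale_mask],
                                          0.0, None)
            loss = dE_e + dE_cont + dE_disc
        E_new = np.maximum(Ei - loss * 1e-6, 0.0)

        # deposit tallies at the step midpoint
        depth_mid = np.clip(xi + 0.5 * ux * ds, 0.0, total_depth - eps)
        b = np.minimum((depth_mid / binw_mm).astype(np.int64), n_bins - 1)
        np.add.at(ioniz, b, dE_e)
        np.add.at(recoil_mat, (m, b), dE_cont)

        # advance positions
        x[idx] = xi + ux * ds
        y[idx] += uy[idx] * ds
        z[idx] += uz[idx] * ds

        # Highland multiple scattering
        beta2, pc = _kinematics(np.maximum(E_mid, 0.5 * cutoff), A1)
        t_rel = ds / tables.X0_mm[m]
        log_arg = np.maximum(t_rel * Z1**2 / beta2, 1e-12)
        corr = np.maximum(1.0 + 0.038 * np.log(log_arg), 0.25)
        theta0 = 13.6 / (np.sqrt(beta2) * pc) * Z1 * np.sqrt(t_rel) * corr
        uy[idx] += rng.standard_normal(idx.size) * theta0
        uz[idx] += rng.standard_normal(idx.size) * theta0

        # terminations
        E[idx] = E_new
        done_stop = E_new <= cutoff
        done_exit = (x[idx] >= total_depth - eps) & ~done_stop
        if np.any(done_stop):
            rows = idx[done_stop]
            bs = np.minimum((np.clip(x[rows], 0.0, total_depth - eps)
                             / binw_mm).astype(np.int64), n_bins - 1)
            ms = np.clip(np.searchsorted(tables.boundaries,
                                         np.clip(x[rows], 0.0, total_depth - eps),
                                         side="right") - 1, 0, n_layers - 1)
            np.add.at(recoil_mat, (ms, bs), E_new[done_stop] * 1e6)
            stopped[rows] = True
            E[rows] = 0.0
            alive[rows] = False
        if np.any(done_exit):
            rows = idx[done_exit]
            exit_E[rows] = E_new[done_exit]
            alive[rows] = False
    else:
        raise RuntimeError("transport failed to terminate (step starvation)")

    if np.any(~np.isfinite(E)):
        raise AssertionError("NaN/inf ion energy encountered (internal bug)")

    # element-resolved recoil: project continuous/residual through shares
    recoil_elem = recoil_disc.copy()
    recoil_elem += tables.cont_share.T @ recoil_mat

    norm = 1.0 / (n_ions * binw_A)
    depth_centers = (np.arange(n_bins) + 0.5) * binw_mm
    record = DepthDoseRecord(
        depth_mm=depth_centers,
        ionization=ioniz * norm,
        recoil_by_element={s: recoil_elem[j] * norm
                           for j, s in enumerate(tables.symbols)},
    )
    ensemble = TrackEnsemble(x_mm=x, y_mm=y, z_mm=z, stopped=stopped,
                             exit_energy_MeV=exit_E)
    events = RecoilEventArrays(
        depth_mm=np.concatenate(ev_depth) if ev_depth else np.empty(0),
        element=np.array(tables.symbols, dtype=object)[
            np.concatenate(ev_elem).astype(np.int64)] if ev_elem
        else np.empty(0, dtype=object),
        T_eV=np.concatenate(ev_T) if ev_T else np.empty(0),
    )

    E0_eV = projectile.energy_MeV * 1e6
    deposited = float(ioniz.sum() + recoil_mat.sum() + recoil_disc.sum())
    transmitted = float(exit_E.sum() * 1e6)
    audit = {
        "input_eV": E0_eV * n_ions,
        "ionization_eV": float(ioniz.sum()),
        "recoil_eV": float(recoil_mat.sum() + recoil_disc.sum()),
        "transmitted_eV": transmitted,
        "balance": (deposited + transmitted) / (E0_eV * n_ions) - 1.0,
    }
    return record, ensemble, events, audit


def phantom_hash(phantom: Phantom) -> str:
    """Stable short hash of the phantom definition (for provenance)."""
    from .materials import _phantom_to_dict

    text = json.dumps(_phantom_to_dict(phantom), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_simulation(beam: BeamSpec, phantom: Phantom,
                   config: TransportConfig | None = None) -> SimulationResult:
    """Transport ``beam.n_ions`` independent ions and aggregate tallies.

    Identical seed and inputs give identical outputs; tallies are
    normalized per ion.
    """
    config = config or TransportConfig()
    _check_energy(beam.projectile.energy_MeV)
    rng = np.random.Generator(np.random.PCG64(beam.seed))
    record, ensemble, events, audit = _run_ensemble(
        beam.projectile, phantom, config, beam.n_ions, rng
    )
    provenance = {
        "seed": beam.seed,
        "n_ions": beam.n_ions,
        "projectile": {"Z1": beam.projectile.Z1, "A1": beam.projectile.A1,
                       "energy_MeV": beam.projectile.energy_MeV},
        "config": asdict(config),
        "phantom": phantom.name,
        "phantom_hash": phantom_hash(phantom),
    }
    return SimulationResult(beam, config, phantom, record, ensemble, events,
                            audit, provenance)


@dataclass
class Track:
    """Single-ion outcome from :func:`transport_ion`."""

    x_mm: float
    y_mm: float
    z_mm: float
    stopped: bool
    exit_energy_MeV: float
    deposited_eV: float


def transport_ion(projectile: ProjectileSpec, phantom: Phantom,
                  config: TransportConfig | None = None,
                  rng_stream: np.random.Generator | int = 0) -> Track:
    """Transport one ion; ``rng_stream`` is a Generator or an integer seed."""
    config = config or TransportConfig()
    _check_energy(projectile.energy_MeV)
    rng = (rng_stream if isinstance(rng_stream, np.random.Generator)
           else np.random.Generator(np.random.PCG64(rng_stream)))
    record, ensemble, _, audit = _run_ensemble(projectile, phantom, config, 1, rng)
    deposited = audit["ionization_eV"] + audit["recoil_eV"]
    return Track(float(ensemble.x_mm[0]), float(ensemble.y_mm[0]),
                 float(ensemble.z_mm[0]), bool(ensemble.stopped[0]),
                 float(ensemble.exit_energy_MeV[0]), deposited)


def default_scan_energies() -> np.ndarray:
    """The default beam-energy scan: 354 to 376 MeV in 2 MeV steps."""
    return np.arange(354.0, 377.0, 2.0)


def energy_scan(energies, phantom: Phantom, n_ions: int = 10_000,
                seed: int = 0, config: TransportConfig | None = None,
                projectile_template: ProjectileSpec | None = None,
                log=None) -> list[SimulationResult]:
    """Run one simulation per beam energy with deterministic derived seeds."""
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    if energies.size == 0:
        raise ValueError("energy list is empty")
    for e in energies:
        _check_energy(float(e))
    tmpl = projectile_template or ProjectileSpec()
    # derived per-energy seeds, deterministic in the master seed
    child_seeds = np.random.SeedSequence(seed).generate_state(energies.size) % (2**31)
    results = []
    for e, s in zip(energies, child_seeds):
        proj = ProjectileSpec(tmpl.Z1, tmpl.A1, float(e))
        beam = BeamSpec(projectile=proj, n_ions=n_ions, seed=int(s))
        if log is not None:
            log.info("transporting %d ions at %.1f MeV through %s",
                     n_ions, e, phantom.name)
        results.append(run_simulation(beam, phantom, config))
    return results


# ---------------------------------------------------------------------------
# CSV output with provenance headers
# ---------------------------------------------------------------------------

def _write_with_header(df, provenance: dict, dest) -> None:
    header = "# " + json.dumps(provenance, sort_keys=True) + "\n"
    if hasattr(dest, "write"):
        dest.write(header)
        df.to_csv(dest, index=False, float_format="%.10g")
    else:
        with open(dest, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.10g")


def write_depth_dose_csv(result: SimulationResult, dest) -> None:
    _write_with_header(result.depth_dose.to_frame(), result.provenance, dest)


def write_endpoints_csv(result: SimulationResult, dest) -> None:
    _write_with_header(result.ensemble.to_frame(), result.provenance, dest)
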