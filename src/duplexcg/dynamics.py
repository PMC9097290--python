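"""Langevin dynamics of the coarse-grained duplex under mechanical protocols.

The equations of motion are integrated with the BAOAB splitting of the
Langevin equation, which samples the configurational ensemble accurately at
the large time steps the stiff harmonic network allows (20 fs by default,
with a thermostat damping time of 20 ps at 300 K).  Identical seeds yield
bit-identical trajectories.

Mechanical protocols add external forces and restraints each step:

* ``BenchmarkPull`` — opposite forces of magnitude f on the sugar centers of
  the second and second-to-last base pairs, directed along the line joining
  the two centers (re-evaluated every step).
* ``StretchTorsion`` — the bottom two base pairs (all their beads) tethered
  harmonically to their initial positions; a constant +z force on the sugar
  center of the second base pair from the top, whose x, y coordinates are
  harmonically restrained to keep the molecule on the z axis; a constant
  torque about z realized as a balanced tangential force couple on all beads
  of the two top base-pair levels (sum F = 0, sum r x F = tau z, solved each
  step).
* ``TwistBend`` — one end tethered as above, +z force on the free end with no
  lateral restraint, so the molecule is free to bend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .constants import BEAD_MASSES, CONSTANTS, FTM2A, KCAL_MOL_A_TO_PN, MVSQ2E
from .energy import EnergyModel
from .forcefield import ForceFieldParameters
from .topology import CGStructure, bead_type_label


class InstabilityError(RuntimeError):
    pass


class ProtocolError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Run parameters (defaults follow the model's standard conditions)."""

    T: float = 300.0              # K
    tau_damp_ps: float = 20.0     # Langevin damping time
    dt_fs: float = 20.0           # integration step
    I: float = 150.0              # ionic strength, mM
    seed: int = 0
    duration_ns: float = 1.0
    discard_ns: float = 0.0       # equilibration discarded from analysis
    tether_k: float = 100.0       # kcal/mol/A^2 (U = k dx^2 convention)
    force_pN: float = 0.0
    torque_pN_nm: float = 0.0
    sample_every: int = 500       # steps between stored frames
    electrostatics_T: Optional[float] = None  # Debye length temperature, if
                                              # different from the thermostat

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.discard_ns >= self.duration_ns and self.duration_ns > 0:
            raise ValueError("discard must be smaller than duration")
        if self.tether_k < 0:
            raise ValueError("tether_k must be nonnegative")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ns * 1e6 / self.dt_fs))

    @property
    def n_discard_steps(self) -> int:
        return int(round(self.discard_ns * 1e6 / self.dt_fs))


@dataclass
class Trajectory:
    """Stored frames (Angstrom) with timestamps and run metadata."""

    frames: np.ndarray            # (n_frames, N, 3)
    times_fs: np.ndarray
    force_pN: float
    torque_pN_nm: float
    config: SimulationConfig
    kinetic_energy: np.ndarray | None = None   # kcal/mol per frame
    potential_energy: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def after_discard(self) -> np.ndarray:
        """Frames recorded after the configured equilibration window."""
        t0 = self.config.discard_ns * 1e6
        return self.frames[self.times_fs >= t0]

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames", data=self.frames, compression="gzip")
            fh.create_dataset("times_fs", data=self.times_fs)
            if self.kinetic_energy is not None:
                fh.create_dataset("kinetic_energy", data=self.kinetic_energy)
            if self.potential_energy is not None:
                fh.create_dataset("potential_energy", data=self.potential_energy)
            fh.attrs["force_pN"] = self.force_pN
            fh.attrs["torque_pN_nm"] = self.torque_pN_nm
            for k, v in vars(self.config).items():
                if v is not None:
                    fh.attrs[f"config_{k}"] = v

    @classmethod
    def load_h5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            cfg_kwargs = {k[len("config_"):]: v for k, v in fh.attrs.items()
                          if k.startswith("config_")}
            cfg_kwargs = {k: (int(v) if k in ("seed", "sample_every") else float(v))
                          for k, v in cfg_kwargs.items()}
            return cls(
                frames=fh["frames"][...],
                times_fs=fh["times_fs"][...],
                force_pN=float(fh.attrs["force_pN"]),
                torque_pN_nm=float(fh.attrs["torque_pN_nm"]),
                config=SimulationConfig(**cfg_kwargs),
                kinetic_energy=fh["kinetic_energy"][...] if "kinetic_energy" in fh else None,
                potential_energy=fh["potential_energy"][...] if "potential_energy" in fh else None,
            )


def _pn_to_internal(f_pN: float) -> float:
    return f_pN / KCAL_MOL_A_TO_PN


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

class Protocol:
    """External force rule; subclasses implement ``forces(coords)``."""

    def forces(self, coords: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class FreeDynamics(Protocol):
    def forces(self, coords):
        return np.zeros_like(coords)


class BenchmarkPull(Protocol):
    """Stretching forces +-f on the sugar centers of base pairs 2 and n-1."""

    def __init__(self, structure: CGStructure, f_pN: float):
        if structure.n < 4:
            raise ProtocolError("benchmark pulling needs at least 4 base pairs")
        self.low = [structure.bead_id("S", s, 2) for s in (1, 2)]
        self.high = [structure.bead_id("S", s, structure.n - 1) for s in (1, 2)]
        self.f = _pn_to_internal(f_pN)

    def forces(self, coords):
        f = np.zeros_like(coords)
        if self.f == 0.0:
            return f
        xi_low = coords[self.low].mean(axis=0)
        xi_high = coords[self.high].mean(axis=0)
        u = xi_low - xi_high
        u = u / np.linalg.norm(u)
        # stretch: pull the two group centers apart along their joining line
        f[self.low] += 0.5 * self.f * u
        f[self.high] -= 0.5 * self.f * u
        return f


class _TetheredBase(Protocol):
    """Common tether of the bottom two base-pair levels (all their beads)."""

    def __init__(self, structure: CGStructure, coords0: np.ndarray,
                 tether_k: float = 100.0):
        ids = []
        for i in (1, 2):
            for role in ("S", "B", "P"):
                for s in (1, 2):
                    if structure.has_bead(role, s, i):
                        ids.append(structure.bead_id(role, s, i))
        self.tether_ids = np.array(sorted(ids))
        self.tether_ref = coords0[self.tether_ids].copy()
        self.k = tether_k

    def _tether_forces(self, coords, f):
        dx = coords[self.tether_ids] - self.tether_ref
        f[self.tether_ids] -= 2.0 * self.k * dx


class StretchTorsion(_TetheredBase):
    def __init__(self, structure: CGStructure, coords0: np.ndarray,
                 f_pN: float = 0.0, tau_pN_nm: float = 0.0,
                 tether_k: float = 100.0, restrain_xy: bool = True):
        if structure.n < 6:
            raise ProtocolError("stretch-torsion needs at least 6 base pairs")
        super().__init__(structure, coords0, tether_k)
        n = structure.n
        self.pull_ids = np.array([structure.bead_id("S", s, n - 1) for s in (1, 2)])
        self.pull_ref_xy = coords0[self.pull_ids].mean(axis=0)[:2].copy()
        self.restrain_xy = restrain_xy
        self.f = _pn_to_internal(f_pN)
        self.tau = tau_pN_nm * 10.0 / KCAL_MOL_A_TO_PN  # pN nm -> kcal/mol (torque about z)
        ids = []
        for i in (n, n - 1):
            for role in ("S", "B", "P"):
                for s in (1, 2):
                    if structure.has_bead(role, s, i):
                        ids.append(structure.bead_id(role, s, i))
        self.torque_ids = np.array(sorted(ids))

    def forces(self, coords):
        f = np.zeros_like(coords)
        self._tether_forces(coords, f)
        # pulling force +z shared by the two sugars of the pulled pair
        f[self.pull_ids, 2] += 0.5 * self.f
        if self.restrain_xy:
            center_xy = coords[self.pull_ids, :2].mean(axis=0)
            f[self.pull_ids, :2] -= 2.0 * self.k * (center_xy - self.pull_ref_xy) \
                / len(self.pull_ids)
        if self.tau != 0.0:
            f += self.torque_couple(coords)
        return f

    def torque_couple(self, coords):
        """Tangential force couple with sum F = 0 and z-torque exactly tau."""
        f = np.zeros_like(coords)
        rho = coords[self.torque_ids, :2]
        rho_rel = rho - rho.mean(axis=0)
        denom = float(np.sum(rho_rel**2))
        if denom < 1e-12:
            raise ProtocolError("torque group collapsed onto the z axis")
        lam = self.tau / denom
        f[self.torque_ids, 0] = -lam * rho_rel[:, 1]
        f[self.torque_ids, 1] = lam * rho_rel[:, 0]
        return f


class TwistBend(StretchTorsion):
    """Tethered base, +z pull on the free end, no lateral restraint."""

    def __init__(self, structure: CGStructure, coords0: np.ndarray,
                 f_pN: float = 0.0, tether_k: float = 100.0):
        super().__init__(structure, coords0, f_pN=f_pN, tau_pN_nm=0.0,
                         tether_k=tether_k, restrain_xy=False)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def bead_masses(structure: CGStructure) -> np.ndarray:
    return np.array([BEAD_MASSES[bead_type_label(b)] for b in structure.beads])


def run_langevin(structure: CGStructure, params: ForceFieldParameters,
                 config: SimulationConfig, protocol: Protocol | None = None,
                 coords0: np.ndarray | None = None,
                 model: EnergyModel | None = None,
                 force_threshold: float = 1e5) -> Trajectory:
    """Integrate Langevin dynamics and return the sampled trajectory.

    The Debye length is computed at ``config.electrostatics_T`` (defaulting
    to the thermostat temperature), which allows quenches that keep the
    screening of the temperature of interest.
    """
    x = np.array(coords0 if coords0 is not None else structure.coords, dtype=float)
    if x is None or x.shape != (structure.n_beads, 3):
        raise ValueError("valid starting coordinates are required")
    protocol = protocol or FreeDynamics()
    if model is None:
        elec_T = config.electrostatics_T or config.T
        model = EnergyModel(structure, params, T=elec_T, I=config.I)

    m = bead_masses(structure)[:, None]
    dt = config.dt_fs
    gamma = 1.0 / (config.tau_damp_ps * 1000.0)
    c1 = math.exp(-gamma * dt)
    kT = CONSTANTS.kB_kcal_mol * config.T
    sigma_v = np.sqrt(kT / m * FTM2A)
    c2 = math.sqrt(1.0 - c1 * c1)

    rng = np.random.default_rng(config.seed)
    v = rng.normal(0.0, 1.0, x.shape) * sigma_v if config.T > 0 else np.zeros_like(x)

    def eval_forces(xc):
        e, f = model.compute(xc)
        f += protocol.forces(xc)
        fmax = np.abs(f).max()
        if not np.isfinite(fmax) or fmax > force_threshold:
            raise InstabilityError(
                f"force blow-up (|F|max = {fmax:.3g} kcal/mol/A)")
        return e, f

    try:
        energy, forces = eval_forces(x)
    except InstabilityError as err:
        raise InstabilityError(f"step 0: {err}") from None
    n_steps = config.n_steps
    frames, times, ke_list, pe_list = [], [], [], []

    def record(step):
        frames.append(x.copy())
        times.append(step * dt)
        ke_list.append(float(0.5 * MVSQ2E * np.sum(m * v * v)))
        pe_list.append(energy)

    record(0)
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * forces / m * FTM2A
        x += 0.5 * dt * v
        if config.T > 0:
            v = c1 * v + c2 * sigma_v * rng.normal(0.0, 1.0, x.shape)
        else:
            v *= c1
        x += 0.5 * dt * v
        try:
            energy, forces = eval_forces(x)
        except InstabilityError as err:
            raise InstabilityError(f"step {step}: {err}") from None
        v += 0.5 * dt * forces / m * FTM2A
        if step % config.sample_every == 0 or step == n_steps:
            record(step)

    return Trajectory(
        frames=np.array(frames),
        times_fs=np.array(times),
        force_pN=config.force_pN,
        torque_pN_nm=config.torque_pN_nm,
        config=config,
        kinetic_energy=np.array(ke_list),
        potential_energy=np.array(pe_list),
    )


# ---------------------------------------------------------------------------
# protocol drivers
# ---------------------------------------------------------------------------

def protocol_benchmark_pull(structure: CGStructure, f_pN: float) -> BenchmarkPull:
    return BenchmarkPull(structure, f_pN)


def protocol_stretch_torsion(structure: CGStructure, coords0: np.ndarray,
                             f_pN: float, tau_pN_nm: float,
                             tether_k: float = 100.0) -> StretchTorsion:
    return StretchTorsion(structure, coords0, f_pN, tau_pN_nm, tether_k)


def protocol_twist_bend(structure: CGStructure, coords0: np.ndarray,
                        f_pN: float, tether_k: float = 100.0) -> TwistBend:
    return TwistBend(structure, coords0, f_pN=f_pN, tether_k=tether_k)


def protocol_quench_ground_state(structure: CGStructure,
                                 params: ForceFieldParameters,
                                 config: SimulationConfig,
                                 n_restarts: int = 100,
                                 hot_ns: float = 0.05,
                                 quench_ns: float = 0.05) -> CGStructure:
    """Minimum-energy conformation by simulated annealing.

    From the starting structure, ``n_restarts`` short runs at the working
    temperature are each quenched to 0 K (keeping the Debye length of the
    working temperature); the final conformation with the smallest total
    energy is returned.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    model = EnergyModel(structure, params, T=config.T, I=config.I)
    best_energy = math.inf
    best_coords = None
    for r in range(n_restarts):
        hot_cfg = replace(config, duration_ns=hot_ns, discard_ns=0.0,
                          seed=config.seed + r, sample_every=10**9)
        hot = run_langevin(structure, params, hot_cfg, model=model)
        cold_cfg = replace(config, T=0.0, electrostatics_T=config.T,
                           duration_ns=quench_ns, discard_ns=0.0,
                           seed=config.seed + r, sample_every=10**9)
        cold = run_langevin(structure, params, cold_cfg, model=model,
                            coords0=hot.frames[-1])
        energy, _ = model.compute(cold.frames[-1])
        if energy < best_energy:
            best_energy = energy
            best_coords = cold.frames[-1]
    return structure.with_coords(best_coords)
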