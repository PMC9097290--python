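"""Shared fixtures.

The thermal trajectory is session-scoped: several tests (equipartition,
Boltzmann inversion, helical statistics) read the same 0.3 ns run of a 12-bp
toy duplex instead of each paying for their own simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from duplexcg import dynamics, fixtures
from duplexcg.topology import Bead


@pytest.fixture(scope="session")
def toy_ff():
    return fixtures.toy_force_field()


@pytest.fixture(scope="session")
def helix21():
    """21-bp ideal helix with the canonical fixture parameters."""
    return fixtures.ideal_helix_coords(("ACGT" * 6)[:21], rise=3.4, twist=34.3,
                                       radius=10.0)


@pytest.fixture(scope="session")
def thermal_run(toy_ff):
    """0.3 ns, 300 K run of a 12-bp toy duplex (strong thermostat coupling so
    kinetic averages decorrelate quickly)."""
    structure = fixtures.ideal_helix_coords("ACGTACGTACGT")
    config = dynamics.SimulationConfig(duration_ns=0.3, discard_ns=0.05,
                                       seed=1234, sample_every=25,
                                       tau_damp_ps=2.0)
    traj = dynamics.run_langevin(structure, toy_ff, config)
    return structure, traj


@pytest.fixture(scope="session")
def fine_step_run(toy_ff):
    """Short 300 K run at dt = 5 fs: with the fastest normal modes well
    resolved, kinetic averages probe the thermostat without the O((w dt)^2)
    kinetic-temperature bias of the production step."""
    structure = fixtures.ideal_helix_coords("ACGTACGTACGT")
    config = dynamics.SimulationConfig(duration_ns=0.1, discard_ns=0.01,
                                       seed=77, sample_every=10, dt_fs=5.0,
                                       tau_damp_ps=0.2)
    traj = dynamics.run_langevin(structure, toy_ff, config)
    return structure, traj


class ParallelBonds:
    """Stand-in energy model: ``n`` independent harmonic bonds.

    Beads 2i and 2i+1 are bonded with U = k (r - r0)^2 and nothing else, so
    every bond samples the single-term Boltzmann density exactly.
    """

    def __init__(self, n_bonds: int, k: float, r0: float, spacing: float = 100.0):
        self.n_bonds = n_bonds
        self.k = k
        self.r0 = r0
        self.beads = [Bead("S", 1, i + 1, "") for i in range(2 * n_bonds)]
        self.n_beads = 2 * n_bonds
        x = np.zeros((self.n_beads, 3))
        x[0::2, 0] = np.arange(n_bonds) * spacing
        x[1::2, 0] = np.arange(n_bonds) * spacing
        x[1::2, 2] = r0
        self.coords = x

    def compute(self, x):
        d = x[1::2] - x[0::2]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.r0
        f = np.zeros_like(x)
        coef = (2.0 * self.k * dr / r)[:, None] * d
        f[0::2] += coef
        f[1::2] -= coef
        return float(np.sum(self.k * dr * dr)), f

    def bond_lengths(self, frames: np.ndarray) -> np.ndarray:
        return np.linalg.norm(frames[:, 1::2] - frames[:, 0::2], axis=-1)


@pytest.fixture(scope="session")
def bond_ensemble():
    """Langevin samples of many independent harmonic bonds (k = 5, r0 = 4)."""
    system = ParallelBonds(n_bonds=400, k=5.0, r0=4.0)
    config = dynamics.SimulationConfig(duration_ns=0.6, discard_ns=0.1,
                                       seed=99, sample_every=100,
                                       tau_damp_ps=0.5)
    traj = dynamics.run_langevin(system, None, config, model=system,
                                 coords0=system.coords)
    samples = system.bond_lengths(traj.after_discard()).ravel()
    return system, samples
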